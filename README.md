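# ropvision

Vessel-oriented enhancement of wide-field neonatal fundus photographs.

Screening for retinopathy of prematurity (ROP) relies on wide-field contact
fundus cameras whose images of the immature eye often have poor contrast: in
aggressive posterior ROP (APROP) the vascular edge, capillary-nonperfusion
("bald") zones, tortuous loops, hemorrhages and flat neovascularization can be
hard to see, and where the visible vessels *end* decides the disease zone and
the extent of laser treatment.  `ropvision` implements three complementary
enhancement protocols for such images, together with a synthetic fundus
phantom generator and ground-truth metrics so that every stage is testable
without patient data.  It is aimed at researchers in retinal image analysis
and at engineers building ROP reading/telemedicine pipelines.

## The protocols

All three start from the green plane G of the RGB photograph (maximal
vessel-to-background contrast), noise-filtered with explicit Perona–Malik
anisotropic diffusion, I ← I + λ Σ_d g(|∇_d I|)∇_d I with conductance
g(s) = exp(−(s/κ)²), which smooths background while preserving vessel edges.

- **GE (Grey Enhanced)** — contrast-limited adaptive histogram equalization
  over 21×21-pixel areas of the filtered plane, yielding the enhanced plane
  G′.
- **CE (Color Enhanced)** — G is replaced by a graded blend
  (1 − g/10)·G + (g/10)·G′ for grade g ∈ {0..10}, retaining the original red
  and blue channels bit-exactly; grades 2, 4, 6, 8 are the usual working set.
- **VNM (Vesselness Measure)** — multiscale Frangi-style tubularity from the
  scale-normalized Hessian eigenvalues (|λ₁| ≤ |λ₂|),
  V = exp(−R_b²/2β²)(1 − exp(−S²/2c²)) with R_b = |λ₁|/|λ₂| and
  S = √(λ₁²+λ₂²), maximized over scales σ = d/4 for vessel diameters d in the
  vessel-diameter search criteria (VDSC), and rendered as bright linear
  structures on a black background — an angiogram-like view of the vascular
  tree.  By construction it also lights up laser scars and the circular field
  edge ("everything tubular"); see `docs/methods.md`.

The pipeline stages are also exposed as scikit-learn-style transformers
(`GreenExtractor`, `AnisotropicDiffusion`, `LocalContrastEnhancer`,
`GreyEnhancer`, `ColorEnhancer`, `VesselnessFilter`) that compose with
`sklearn.pipeline`.

## Worked example

Generate a 512² phantom (seed 0), run all three protocols on it, and score
them against the phantom's ground truth:

```sh
ropvision phantom --seed 0 -o phantom_out
ropvision all phantom_out/phantom.png -o enhanced
ropvision evaluate --seed 0 -o eval_out
```

The `all` run writes one GE image, one CE image per default grade (2, 4, 6,
8) and one VNM image, plus a `params.yaml` reproducing the run:

```
phantom_ce2.png  phantom_ce4.png  phantom_ce6.png  phantom_ce8.png
phantom_ge.png   phantom_vnm.png  params.yaml      run.log
```

`evaluate` prints (and writes to `eval_out/report.txt`):

```
dice = 0.822121
centerline_sensitivity = 0.914132
anterior_extent_measured = 200.159936
anterior_extent_error = -0.142336
contrast_improvement_index = 1.416245
```

Reading these numbers: the binarized VNM map overlaps the true vessel mask
with Dice 0.82; 91% of true centerline points (diameters 2–12 px, the VDSC
range) are detected within 2 px; the anterior extent of the detected
vasculature lands within 0.15 px of the true value (200.2 px from the disc);
and GE raises RMS contrast around the vessels by a factor of 1.42 over the
raw green plane.

Python API equivalent:

```python
import ropvision as rv

ph  = rv.generate_phantom(rv.PhantomConfig(seed=0))
ge  = rv.grey_enhanced(ph.image)
ce4 = rv.color_enhanced(ph.image, grade=4)
vnm = rv.vesselness_measure(rv.anisotropic_diffusion(rv.extract_green(ph.image)))
report = rv.evaluate_protocols(ph, rv.binarize_vessels(vnm), ge,
                               diameter_filter=(2, 12))
```

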