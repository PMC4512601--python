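# Methods

`ropvision` implements three enhancement protocols for wide-field fundus
photographs of infants screened for retinopathy of prematurity (ROP), plus a
synthetic phantom generator and evaluation metrics that make every stage
testable without patient data.  This note records the models, the parameters
that matter, and the design choices made where the design was genuinely open.

## Pipeline

All protocols start from the green plane G of the 8-bit RGB photograph, which
carries the strongest vessel-to-background contrast (haemoglobin absorbs
green light).  Intermediate planes are kept in floating point on the 0–255
scale; quantization (round half up, clamp) happens only on export, so no
iteration-order rounding drift enters the results.

### Edge-preserving noise filtering

Explicit Perona–Malik diffusion with a 4-neighbour stencil:

    I ← I + λ Σ_{d∈{N,S,E,W}} g(|∇_d I|) ∇_d I,
    g(s) = exp(−(s/κ)²)  or  1/(1 + (s/κ)²).

Boundaries are reflective (Neumann), which makes the scheme flux-conserving
(mean intensity preserved) and keeps the dark frame of a circular camera
field from bleeding inwards.  λ ≤ 0.25 is required for stability of the
explicit scheme; default λ = 0.2, 10 iterations, exponential conductance.

The conductance threshold κ separates "noise" gradients (diffused away) from
"edge" gradients (preserved).  **Default κ = 10** on the 0–255 scale: sensor
noise at realistic levels (σ ≈ 2–3 grey values) produces neighbour
differences of ~3–4, while the faintest clinically relevant structures —
terminal capillaries a few pixels wide — present edge steps of only ~10–20
grey values.  A larger κ (e.g. 30) erases precisely those capillaries: on the
default phantom, centerline sensitivity of the vesselness output drops from
0.92 (κ=10) to 0.68 (κ=30).  Since recovering small-calibre vessels is the
point of the pipeline, the default sits just above the noise scale.

### Local contrast enhancement (Grey Enhanced, GE)

Contrast-limited adaptive histogram equalization (CLAHE) over 21×21-pixel
areas: the plane is tiled (reflect-padded to a tile multiple), each tile gets
a 256-bin histogram clipped at `clip_limit · N/256` with the excess
redistributed uniformly, and the per-tile equalization mappings are blended
bilinearly at every pixel.  Zero-variance tiles map to themselves, so flat
regions (and all-black images) are fixed points.  Whether the 21×21 "areas"
tile the image or slide per pixel is an open choice; tiling with bilinear
interpolation is the standard CLAHE construction and is what is implemented.
Default clip_limit = 2.0.  The result of filtering + CLAHE is the Grey
Enhanced plane G′.

### Graded recombination (Color Enhanced, CE)

CE substitutes an enhanced green plane into the colour image while retaining
the original red and blue channels bit-exactly.  Grades form a one-parameter
family: grade g ∈ {0..10} blends

    G_out = quantize((1 − g/10) · G + (g/10) · G′),

so grade 0 is the pixel-identical identity and grade 10 is full substitution.
This is the simplest monotone family producing "several grades of outputs";
the conventional working set is grades 2, 4, 6 and 8.  Grade choice is a
clinical reading decision, not automated here.  A documented side effect:
at high grades on noisy input, equalized noise produces spurious bright
("bald") spots that can mimic ischemic zones — the test suite asserts this
behaviour exists rather than hiding it.

### Vesselness Measure (VNM)

Multiscale Frangi-style tubularity on the filtered green plane.  At scale σ,
scale-normalized Hessian eigenvalues (|λ₁| ≤ |λ₂|) are computed by Gaussian
derivative filtering (γ-normalization by σ²); the response is

    V = exp(−R_b²/(2β²)) · (1 − exp(−S²/(2c²))),
    R_b = |λ₁|/|λ₂|,  S = √(λ₁² + λ₂²),

zero wherever λ₂ ≤ 0 (dark-on-bright polarity: vessels are darker than
background in the green plane).  Defaults β = 0.5, c = 15 (0–255 scale).
Gaussian kernels use a wide support (8σ) so residual kernel moments vanish:
the response is then exact on quadratics and invariant to constant intensity
offsets.

The vessel-diameter search criteria (VDSC) give a diameter range
[d_min, d_max]; diameters map to scales via σ = d/4 (the maximal
scale-normalized response of a Gaussian-profile tube of diameter d lies near
σ ≈ d/4, within one log-spaced scale step), with n_scales log-spaced values
and a lower bound σ ≥ 0.5.  Default VDSC 2–12 px, 5 scales — biased toward
the small vessels of interest in ROP.

The per-pixel maximum across scales is floored and rescaled: responses below
**0.01** become exactly 0 (black background), the rest map linearly so the
per-image maximum is 255.  The floor separates diffuse background and
residual noise (responses ≲ 10⁻³ after filtering) from faint terminal
capillaries (responses ≈ 0.02); a larger floor (0.05) was measured to erase
those capillary extensions, defeating its purpose of keeping them while
blacking out the background.  Rescaling is per-image because the 8-bit output
has no absolute calibration.

Known limitation, by construction: laser scars, the circular field edge and
vascular loops are all "tubes" to this measure and light up in the output;
distinguishing them is left to clinical reading (continuity of the vascular
tree).  Raised (out-of-plane) fibrovascular tissue is outside the model.

## Phantom generator

The generator emulates aggressive posterior ROP (APROP) imaging sessions:

- **Background**: bright posterior pole (+25 grey Gaussian bump around the
  disc), then a pale grey-white sheen (+40, smoothstep starting at 0.26·size)
  toward the periphery — the immature avascular retina appears pale — with
  low-frequency choroidal texture (σ ≈ size/24, amplitude 6) that decays with
  distance from the posterior pole, because the avascular periphery is smooth
  and featureless.  Red ≈ 1.3·G + 15, blue ≈ 0.35·G.
- **Vessel tree**: random-walk branches from the disc (default 6 trunks,
  heading jitter 0.10 rad/step with a gentle outward bias), child branches
  spawned stochastically, diameters tapering exponentially from d_max to
  d_min (default 10 → 2 px) as they approach the field margin (0.46·size).
  Tubes are rasterized with anti-aliased circular cross-sections and
  subtracted from green by `vessel_contrast` (default 40) and from red by a
  third of that.  Optical contrast scales with calibre, min(1, d/4): a 2-px
  capillary is half as deep as a trunk — physically, absorption follows the
  blood column thickness — so terminal capillaries are genuinely faint.
- **Loops**: high-curvature near-closed curls (radius 5–9 px, calibre
  2–3 px) appended at branch tips.
- **CNP zones**: ellipses where the background is flattened (and slightly
  paled) and vessels are removed — "bald" nonperfused areas.
- **Hemorrhages**: irregular dark blobs (harmonic-wobbled radius 6–13 px)
  darkening green and red.
- **Laser rings / field aperture** (preset-only): bright rings with a darker
  pigmented rim, and a circular camera field with near-black exterior.
- **Noise and vignette**: additive Gaussian noise per channel (default
  σ = 2); the poor-pupil option multiplies by a radial falloff and applies a
  mild blur.

All masks, centerlines (with per-point diameter) and the true anterior extent
are recorded *before* noise, so ground truth is noise-independent.  All
randomness flows from one seeded generator; identical configs are
bit-identical.  Named presets: `default`, `poor-pupil`, `dense-cnp`,
`thin-capillary` (faint 2-px terminal capillaries, no hemorrhages, σ = 1 —
the regime for the anterior-extent comparison), `laser-rings`.

What the phantom does **not** model: real choroidal vasculature, optics of a
contact wide-field lens, raised ridge/stage-3 elevation, pigmentation
variation between infants, motion blur.  Passing phantom tests therefore
demonstrates correctness of the algorithms under controlled conditions, not
clinical performance.

## Evaluation metrics

- **Dice** between a binarized vesselness map (default 8-bit threshold 25)
  and the true vessel mask; 1.0 when both are empty.
- **Centerline sensitivity**: fraction of centerline points (optionally
  filtered to a diameter range) with a detected pixel within Chebyshev
  distance 2; the square neighbourhood is cheap and its rotation bias is
  negligible at this tolerance.
- **Anterior extent**: maximum Euclidean distance of any detected pixel from
  the disc centre — the quantity that decides how far anteriorly the
  vascularized retina is read, and hence zone classification.
- **Contrast improvement index**: ratio of RMS contrast (intensity standard
  deviation) after/before within the vessel ROI dilated by 5 px.
- **Matched-FPR baseline**: the fair "unprocessed image" comparator for the
  anterior-extent question is a global dark threshold on the raw green plane,
  with the threshold set so the baseline admits the same number of background
  false positives as the vesselness detection.  It uses no vesselness
  machinery.  On the thin-capillary preset the vesselness detection reaches
  the capillary tips while the matched global threshold cannot follow faint
  vessels onto the pale periphery — the mechanism by which the enhanced
  reading places the vascular edge more anteriorly.  This is asserted as a
  direction (≥), not as a clinical claim.

## Problem sizes and numerical choices

Tests and the acceptance script run on 512² phantoms (and 128² for CLI
round-trips), 5 vesselness scales, 10 diffusion iterations; oracle
comparisons (loop-based diffusion and CLAHE re-implementations,
`np.linalg.eigvalsh`, finite differences) use ≤ 64² inputs.  Ties in
quantization are settled by round-half-up everywhere.  Degenerate inputs are
defined, not special-cased ad hoc: zero-iteration diffusion is the identity,
constant planes are fixed points of every stage, empty masks give extent 0,
and Dice/sensitivity of empty-vs-empty is 1.
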