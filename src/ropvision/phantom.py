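"""Synthetic wide-field fundus phantoms with pixel-level ground truth.

The generator emulates the posterior-pole appearance of aggressive posterior
ROP on a contact wide-field camera: a bright fundus background with
low-frequency choroidal texture, a branching vessel tree growing out of the
optic disc and darker than background in the green channel, tortuous terminal
loops at the vascular-avascular junction, hemorrhage blobs, capillary-
nonperfusion ("bald") zones where the background is featureless and no vessels
run, additive sensor noise, and optionally a peripheral vignette/blur
emulating a poorly dilating pupil plus a circular camera field edge and
laser-scar rings.

Two deliberate departures from a generic retina model reflect the disease
being emulated: choroidal texture amplitude decays with distance from the
posterior pole (the immature avascular periphery is smooth and featureless),
and vessel optical contrast scales with calibre (min(1, d/4)), so terminal
capillaries are genuinely faint — the regime in which vesselness filtering
outperforms raw intensity thresholding.

Every random draw flows from one seeded generator; identical configs produce
bit-identical phantoms.  All ground-truth masks are recorded before noise is
added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import quantize_u8

__all__ = [
    "PhantomConfig",
    "Phantom",
    "GenerationError",
    "generate_phantom",
    "preset_config",
    "PRESETS",
]

#: spacing (pixels) between consecutive recorded centerline samples
CENTERLINE_STEP = 1.5

#: vessel contrast is scaled by min(1, diameter / CONTRAST_REF_DIAMETER)
CONTRAST_REF_DIAMETER = 4.0


class GenerationError(ValueError):
    """Raised when a configuration demands more features than fit the field."""


@dataclass
class PhantomConfig:
    """Generator parameters; defaults describe a typical posterior-pole session.

    size : square image side in pixels.
    disc_center : (row, col) of the optic disc; image centre when None.
    n_branches : number of primary vessel trunks leaving the disc.
    diameter_range : (min, max) vessel diameter in pixels; trunks start near
        the max and taper toward the min at the periphery.
    vessel_contrast : green-channel depth (grey levels) of a full-calibre
        vessel below the local background.
    n_loops : tortuous terminal loops appended at branch tips.
    n_hemorrhages : irregular dark blobs.
    n_cnp : elliptical capillary-nonperfusion zones (flattened, vessel-free).
    noise_sigma : additive Gaussian noise, grey levels.
    vignette : apply peripheral vignetting and mild blur (poor pupil).
    n_laser_rings : bright laser-scar rings with pigmented rims.
    field_aperture : mask everything outside a circular camera field.
    seed : seed for the single random generator.
    """

    size: int = 512
    disc_center: tuple[int, int] | None = None
    n_branches: int = 6
    diameter_range: tuple[float, float] = (2.0, 10.0)
    vessel_contrast: float = 40.0
    n_loops: int = 3
    n_hemorrhages: int = 2
    n_cnp: int = 2
    noise_sigma: float = 2.0
    vignette: bool = False
    n_laser_rings: int = 0
    field_aperture: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        d_lo, d_hi = self.diameter_range
        if d_lo < 1 or d_lo > d_hi:
            raise ValueError("diameter_range requires 1 <= min <= max")
        if self.vessel_contrast <= 0:
            raise ValueError("vessel_contrast must be positive")
        for name in ("n_branches", "n_loops", "n_hemorrhages", "n_cnp",
                     "n_laser_rings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Phantom:
    """A rendered phantom plus its ground truth."""

    image: np.ndarray                 # uint8 H×W×3
    vessel_mask: np.ndarray           # bool H×W
    centerline: np.ndarray            # float (N, 3): row, col, diameter
    hemorrhage_mask: np.ndarray       # bool H×W
    cnp_mask: np.ndarray              # bool H×W
    disc_center: tuple[int, int]
    true_anterior_extent: float       # max distance of any vessel pixel from disc
    config: PhantomConfig
    field_mask: np.ndarray = None     # bool H×W; all-true without an aperture
    laser_mask: np.ndarray = None     # bool H×W; empty without laser rings


def _check_capacity(cfg: PhantomConfig) -> None:
    field_area = cfg.size * cfg.size
    if cfg.n_cnp * math.pi * 35 * 25 > 0.5 * field_area:
        raise GenerationError("n_cnp: requested nonperfusion zones exceed the field")
    if cfg.n_hemorrhages * math.pi * 13**2 > 0.4 * field_area:
        raise GenerationError("n_hemorrhages: requested hemorrhages exceed the field")
    if cfg.n_branches and cfg.n_loops > 6 * cfg.n_branches:
        raise GenerationError("n_loops: more loops than available branch tips")
    if cfg.n_laser_rings * math.pi * 9**2 > 0.4 * field_area:
        raise GenerationError("n_laser_rings: requested rings exceed the field")


class _Canvas:
    """Accumulates anti-aliased vessel coverage and contrast-weighted depth."""

    def __init__(self, size: int):
        self.size = size
        self.cov = np.zeros((size, size))
        self.depth = np.zeros((size, size))

    def stamp(self, y: float, x: float, diameter: float) -> bool:
        """Max in an anti-aliased disc of the given diameter; False if off-image."""
        size = self.size
        rad = diameter / 2.0
        reach = int(math.ceil(rad + 1.0))
        iy, ix = int(round(y)), int(round(x))
        if iy < 1 or ix < 1 or iy > size - 2 or ix > size - 2:
            return False
        y0, y1 = max(0, iy - reach), min(size, iy + reach + 1)
        x0, x1 = max(0, ix - reach), min(size, ix + reach + 1)
        dy = np.arange(y0, y1, dtype=float) - y
        dx = np.arange(x0, x1, dtype=float) - x
        dist = np.hypot(dy[:, None], dx[None, :])
        a = np.clip(rad + 0.5 - dist, 0.0, 1.0)
        np.maximum(self.cov[y0:y1, x0:x1], a, out=self.cov[y0:y1, x0:x1])
        cscale = min(1.0, diameter / CONTRAST_REF_DIAMETER)
        np.maximum(self.depth[y0:y1, x0:x1], a * cscale,
                   out=self.depth[y0:y1, x0:x1])
        return True


def _grow_tree(cfg: PhantomConfig, rng: np.random.Generator, canvas: _Canvas,
               disc: tuple[int, int], max_r: float):
    """Random-walk vessel tree; returns centerline samples and branch tips."""
    d_lo, d_hi = cfg.diameter_range
    pts: list[tuple[float, float, float]] = []
    tips: list[tuple[float, float, float]] = []
    # per-step taper so a trunk reaches d_lo roughly at the growth boundary
    decay = (d_lo / d_hi) ** (CENTERLINE_STEP / (0.95 * max_r))
    stack: list[tuple[float, float, float, float]] = []
    for b in range(cfg.n_branches):
        ang = 2.0 * math.pi * (b + rng.uniform(0.2, 0.8)) / max(cfg.n_branches, 1)
        diam = d_hi * rng.uniform(0.85, 1.0)
        y = disc[0] + 4.0 * math.sin(ang)
        x = disc[1] + 4.0 * math.cos(ang)
        stack.append((y, x, ang, diam))
    while stack:
        y, x, ang, diam = stack.pop()
        while True:
            if canvas.stamp(y, x, diam):
                pts.append((y, x, diam))
            else:
                tips.append((y, x, ang))
                break
            ang += rng.normal(0.0, 0.10)
            # gentle outward bias keeps branches from doubling back on the disc
            radial = math.atan2(y - disc[0], x - disc[1])
            delta = (radial - ang + math.pi) % (2.0 * math.pi) - math.pi
            ang += 0.08 * delta
            y += CENTERLINE_STEP * math.sin(ang)
            x += CENTERLINE_STEP * math.cos(ang)
            diam *= decay
            rr = math.hypot(y - disc[0], x - disc[1])
            if rr >= max_r or diam < 0.97 * d_lo:
                tips.append((y, x, ang))
                break
            if diam > 1.6 * d_lo and rng.random() < 0.025:
                side = 1.0 if rng.random() < 0.5 else -1.0
                child_ang = ang + side * rng.uniform(0.35, 0.9)
                stack.append((y, x, child_ang, diam * rng.uniform(0.6, 0.75)))
                diam *= 0.9
    return pts, tips


def _add_loops(cfg: PhantomConfig, rng: np.random.Generator, canvas: _Canvas,
               tips: list, pts: list) -> None:
    if cfg.n_loops == 0 or not tips:
        return
    for k in range(cfg.n_loops):
        ty, tx, tang = tips[k % len(tips)]
        loop_r = rng.uniform(5.0, 9.0)
        d_loop = rng.uniform(2.0, 3.0)
        side = 1.0 if rng.random() < 0.5 else -1.0
        # circle tangent to the tip direction
        cy = ty + side * loop_r * math.cos(tang)
        cx = tx - side * loop_r * math.sin(tang)
        theta0 = math.atan2(ty - cy, tx - cx)
        n_steps = max(8, int(1.85 * math.pi * loop_r / CENTERLINE_STEP))
        for t in np.linspace(0.0, side * 1.85 * math.pi, n_steps):
            y = cy + loop_r * math.sin(theta0 + t)
            x = cx + loop_r * math.cos(theta0 + t)
            if canvas.stamp(y, x, d_loop):
                pts.append((y, x, d_loop))


def _ellipse_mask(size: int, center: tuple[float, float], axes: tuple[float, float],
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _blob_mask(size: int, center: tuple[float, float], r0: float,
               rng: np.random.Generator) -> np.ndarray:
    """Irregular blob: base radius wobbled by low-order angular harmonics."""
    amp = rng.uniform(0.1, 0.3, size=3)
    phase = rng.uniform(0.0, 2.0 * math.pi, size=3)
    reach = int(math.ceil(r0 * 1.6)) + 2
    cy, cx = center
    y0, y1 = max(0, int(cy) - reach), min(size, int(cy) + reach + 1)
    x0, x1 = max(0, int(cx) - reach), min(size, int(cx) + reach + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    wobble = 1.0 + sum(a * np.cos((j + 1) * theta + p)
                       for j, (a, p) in enumerate(zip(amp, phase)))
    out = np.zeros((size, size), dtype=bool)
    out[y0:y1, x0:x1] = dist <= r0 * np.clip(wobble, 0.4, 1.8)
    return out


def generate_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Render a phantom and its ground truth; deterministic for a fixed seed."""
    cfg = config or PhantomConfig()
    _check_capacity(cfg)
    size = cfg.size
    disc = cfg.disc_center or (size // 2, size // 2)
    rng = np.random.default_rng(cfg.seed)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    r_disc = np.hypot(yy - disc[0], xx - disc[1])
    centre = ((size - 1) / 2.0, (size - 1) / 2.0)
    r_img = np.hypot(yy - centre[0], xx - centre[1])
    max_r = 0.46 * size

    # --- background: bright posterior pole, then the pale grey-white sheen of
    # the immature avascular periphery; choroidal texture is posterior-weighted
    # (the avascular periphery is smooth and featureless)
    g_bg = 150.0 + 25.0 * np.exp(-((r_disc / (0.45 * size)) ** 2))
    s = np.clip((r_disc - 0.26 * size) / (0.17 * size), 0.0, 1.0)
    g_bg += 40.0 * s * s * (3.0 - 2.0 * s)
    tex = gaussian_filter(rng.standard_normal((size, size)), size / 24.0)
    tex *= 6.0 / max(tex.std(), 1e-12)
    g_bg = g_bg + tex * np.exp(-((r_disc / (0.35 * size)) ** 2))
    r_bg = np.clip(g_bg * 1.3 + 15.0, 0.0, 255.0)
    b_bg = g_bg * 0.35

    # --- vessel tree, loops
    canvas = _Canvas(size)
    pts, tips = _grow_tree(cfg, rng, canvas, disc, max_r)
    _add_loops(cfg, rng, canvas, tips, pts)

    # --- capillary nonperfusion zones: flatten texture, remove vessels
    cnp_mask = np.zeros((size, size), dtype=bool)
    for _ in range(cfg.n_cnp):
        rr = rng.uniform(0.3, 0.8) * max_r
        ang = rng.uniform(0.0, 2.0 * math.pi)
        center = (disc[0] + rr * math.sin(ang), disc[1] + rr * math.cos(ang))
        axes = (rng.uniform(16.0, 34.0), rng.uniform(10.0, 24.0))
        theta = rng.uniform(0.0, math.pi)
        cnp_mask |= _ellipse_mask(size, center, axes, theta)
    if cnp_mask.any():
        g_bg = np.where(cnp_mask, gaussian_filter(g_bg, 6.0) + 5.0, g_bg)
        canvas.cov[cnp_mask] = 0.0
        canvas.depth[cnp_mask] = 0.0

    # --- hemorrhages
    hem_mask = np.zeros((size, size), dtype=bool)
    for _ in range(cfg.n_hemorrhages):
        rr = rng.uniform(0.2, 0.75) * max_r
        ang = rng.uniform(0.0, 2.0 * math.pi)
        center = (disc[0] + rr * math.sin(ang), disc[1] + rr * math.cos(ang))
        hem_mask |= _blob_mask(size, center, rng.uniform(6.0, 13.0), rng)
    hem_soft = gaussian_filter(hem_mask.astype(float), 1.0)

    # --- laser-scar rings (bright centre band with a darker pigmented rim)
    laser_mask = np.zeros((size, size), dtype=bool)
    laser_bright = np.zeros((size, size))
    laser_dark = np.zeros((size, size))
    for _ in range(cfg.n_laser_rings):
        rr = rng.uniform(0.55, 0.85) * max_r
        ang = rng.uniform(0.0, 2.0 * math.pi)
        cy = disc[0] + rr * math.sin(ang)
        cx = disc[1] + rr * math.cos(ang)
        ring_r = rng.uniform(5.0, 9.0)
        d = np.hypot(yy - cy, xx - cx)
        laser_bright += 60.0 * np.exp(-(((d - ring_r) / 1.2) ** 2))
        laser_dark += 25.0 * np.exp(-(((d - (ring_r + 2.5)) / 1.2) ** 2))
        laser_mask |= np.abs(d - ring_r) <= 4.0

    # --- ground truth (pre-noise)
    vessel_mask = canvas.cov >= 0.5
    kept = []
    for (py, px, pd) in pts:
        iy, ix = int(round(py)), int(round(px))
        if 0 <= iy < size and 0 <= ix < size and vessel_mask[iy, ix]:
            kept.append((py, px, pd))
    centerline = (np.array(kept, dtype=float) if kept
                  else np.empty((0, 3), dtype=float))
    if vessel_mask.any():
        true_extent = float(r_disc[vessel_mask].max())
    else:
        true_extent = 0.0

    # --- compose channels
    g_ch = g_bg - cfg.vessel_contrast * canvas.depth
    r_ch = r_bg - (cfg.vessel_contrast / 3.0) * canvas.depth
    b_ch = b_bg.copy()
    g_ch -= 60.0 * hem_soft
    r_ch -= 45.0 * hem_soft
    b_ch -= 10.0 * hem_soft
    g_ch += laser_bright - laser_dark
    r_ch += laser_bright - 0.6 * laser_dark
    b_ch += 0.5 * laser_bright

    field_mask = np.ones((size, size), dtype=bool)
    if cfg.field_aperture:
        field_mask = r_img <= 0.47 * size
        for ch in (g_ch, r_ch, b_ch):
            ch *= np.where(field_mask, 1.0, 0.04)

    if cfg.vignette:
        fall = 0.3 + 0.7 * np.exp(-((r_img / (0.42 * size)) ** 2))
        g_ch = gaussian_filter(g_ch, 1.2) * fall
        r_ch = gaussian_filter(r_ch, 1.2) * fall
        b_ch = gaussian_filter(b_ch, 1.2) * fall

    if cfg.noise_sigma > 0:
        g_ch = g_ch + rng.normal(0.0, cfg.noise_sigma, (size, size))
        r_ch = r_ch + rng.normal(0.0, cfg.noise_sigma, (size, size))
        b_ch = b_ch + rng.normal(0.0, cfg.noise_sigma, (size, size))

    image = np.stack([quantize_u8(r_ch), quantize_u8(g_ch), quantize_u8(b_ch)],
                     axis=-1)
    return Phantom(
        image=image,
        vessel_mask=vessel_mask,
        centerline=centerline,
        hemorrhage_mask=hem_mask,
        cnp_mask=cnp_mask & ~vessel_mask,
        disc_center=tuple(disc),
        true_anterior_extent=true_extent,
        config=cfg,
        field_mask=field_mask,
        laser_mask=laser_mask,
    )


#: named study conditions
PRESETS: dict[str, PhantomConfig] = {
    "default": PhantomConfig(),
    "poor-pupil": PhantomConfig(vignette=True, noise_sigma=3.0),
    "dense-cnp": PhantomConfig(n_cnp=6),
    # faint terminal capillaries, clean background: the regime behind the
    # anterior-extent (zone reclassification) comparison
    "thin-capillary": PhantomConfig(diameter_range=(2.0, 8.0), n_hemorrhages=0,
                                    n_loops=2, noise_sigma=1.0),
    # laser scars and a circular field edge for the documented-limitation check
    "laser-rings": PhantomConfig(n_laser_rings=6, field_aperture=True,
                                 n_cnp=0, n_hemorrhages=0),
}


def preset_config(name: str, seed: int = 0, size: int | None = None) -> PhantomConfig:
    """A fresh config for a named preset with the given seed (and size)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = replace(PRESETS[name], seed=seed)
    if size is not None:
        cfg = replace(cfg, size=size)
    return cfg
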