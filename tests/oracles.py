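"""Independent, deliberately naive loop-based reference implementations.

These mirror the mathematical definitions of the pipeline operations with
explicit Python loops and share no code with the package; they exist so the
vectorized implementations can be checked against a second, independent path.
"""

from __future__ import annotations

import math

import numpy as np


def perona_malik_loops(values: np.ndarray, iterations: int, kappa: float,
                       lam: float, kind: str = "exponential") -> np.ndarray:
    """Literal 4-neighbour explicit Perona-Malik update, pixel by pixel."""
    a = np.array(values, dtype=float, copy=True)
    h, w = a.shape
    for _ in range(iterations):
        new = a.copy()
        for y in range(h):
            for x in range(w):
                c = a[y, x]
                acc = 0.0
                for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    d = a[yy, xx] - c
                    if kind == "exponential":
                        g = math.exp(-((abs(d) / kappa) ** 2))
                    else:
                        g = 1.0 / (1.0 + (d / kappa) ** 2)
                    acc += g * d
                new[y, x] = c + lam * acc
        a = new
    return a


def _bin255(v: float) -> int:
    return int(min(255, max(0, math.floor(v + 0.5))))


def clahe_loops(values: np.ndarray, window: int, clip_limit: float) -> np.ndarray:
    """Windowed clipped histogram equalization with per-pixel bilinear blending
    of the four surrounding tile mappings, all in explicit loops."""
    h, w = values.shape
    pad_h = (-h) % window
    pad_w = (-w) % window
    padded = np.pad(values, ((0, pad_h), (0, pad_w)), mode="symmetric")
    hp, wp = padded.shape
    nty, ntx = hp // window, wp // window

    maps: dict[tuple[int, int], list[float]] = {}
    for ti in range(nty):
        for tj in range(ntx):
            hist = [0.0] * 256
            lo_bin, hi_bin = 255, 0
            for y in range(ti * window, (ti + 1) * window):
                for x in range(tj * window, (tj + 1) * window):
                    b = _bin255(padded[y, x])
                    hist[b] += 1
                    lo_bin = min(lo_bin, b)
                    hi_bin = max(hi_bin, b)
            if lo_bin == hi_bin:
                maps[(ti, tj)] = [float(v) for v in range(256)]
                continue
            n = window * window
            clip = clip_limit * n / 256.0
            excess = sum(max(c - clip, 0.0) for c in hist)
            hist = [min(c, clip) + excess / 256.0 for c in hist]
            cdf = []
            acc = 0.0
            for c in hist:
                acc += c
                cdf.append(acc)
            lo = cdf[0]
            maps[(ti, tj)] = [(c - lo) / (cdf[-1] - lo) * 255.0 for c in cdf]

    out = np.zeros((hp, wp))
    for y in range(hp):
        fy = (y - (window - 1) / 2.0) / window
        i0 = math.floor(fy)
        ty = fy - i0
        i0c = min(max(i0, 0), nty - 1)
        i1c = min(max(i0 + 1, 0), nty - 1)
        for x in range(wp):
            fx = (x - (window - 1) / 2.0) / window
            j0 = math.floor(fx)
            tx = fx - j0
            j0c = min(max(j0, 0), ntx - 1)
            j1c = min(max(j0 + 1, 0), ntx - 1)
            b = _bin255(padded[y, x])
            top = (1 - tx) * maps[(i0c, j0c)][b] + tx * maps[(i0c, j1c)][b]
            bot = (1 - tx) * maps[(i1c, j0c)][b] + tx * maps[(i1c, j1c)][b]
            out[y, x] = (1 - ty) * top + ty * bot
    return out[:h, :w]


def centerline_sensitivity_loops(mask: np.ndarray, centerline: np.ndarray,
                                 tolerance: int,
                                 diameter_filter: tuple[float, float] | None = None
                                 ) -> float:
    """Per-point exhaustive Chebyshev-neighbourhood scan."""
    mask = np.asarray(mask).astype(bool)
    pts = np.asarray(centerline, dtype=float).reshape(-1, 3)
    if diameter_filter is not None:
        pts = [p for p in pts if diameter_filter[0] <= p[2] <= diameter_filter[1]]
    if len(pts) == 0:
        return 1.0
    h, w = mask.shape
    hits = 0
    for (r, c, _d) in pts:
        ri, ci = int(round(r)), int(round(c))
        ri = min(max(ri, 0), h - 1)
        ci = min(max(ci, 0), w - 1)
        found = False
        for y in range(max(0, ri - tolerance), min(h, ri + tolerance + 1)):
            for x in range(max(0, ci - tolerance), min(w, ci + tolerance + 1)):
                if mask[y, x]:
                    found = True
                    break
            if found:
                break
        hits += found
    return hits / len(pts)


def anterior_extent_loops(mask: np.ndarray, disc_center) -> float:
    """Exhaustive per-pixel max-distance scan."""
    mask = np.asarray(mask).astype(bool)
    best = 0.0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                best = max(best, math.hypot(y - disc_center[0], x - disc_center[1]))
    return best
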