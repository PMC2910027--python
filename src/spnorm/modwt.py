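"""Two-dimensional maximal-overlap discrete wavelet transform and denoising.

The MODWT is the undecimated, shift-invariant variant of the discrete
wavelet transform: every sub-band keeps the input shape, the transform is
defined for arbitrary (non-power-of-2) grid sizes, and circularly shifting
the input shifts every sub-band identically.  The 2D transform is separable:
at level j the level-(j-1) smooth is filtered along rows and columns with
the scaling/wavelet filter pair upsampled by 2^(j-1), with circular boundary
handling, yielding three detail sub-bands per level plus a final smooth.

Filters follow the standard MODWT convention: the unit-norm orthogonal
scaling filter (PyWavelets ``rec_lo``) rescaled by 1/sqrt(2), with the
wavelet filter obtained by the quadrature-mirror relation
h_l = (-1)^l g_{L-1-l}.  For Haar this gives g = (1/2, 1/2) and
h = (1/2, -1/2).

Denoising uses the universal soft-threshold rule: details are shrunk by
lambda = sigma_hat * sqrt(2 ln N), N the cell count and sigma_hat the
MAD-based noise estimate from the level-1 diagonal sub-band — a level that,
for smooth underlying surfaces, is essentially pure noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .layout import ChipLayout

logger = logging.getLogger(__name__)

__all__ = [
    "Modwt2DCoeffs",
    "QuadrantPartition",
    "modwt_filters",
    "modwt2d",
    "imodwt2d",
    "universal_soft_threshold",
    "fill_holes",
    "split_quadrants",
    "denoise_surface",
]


def modwt_filters(wavelet: str = "haar") -> tuple[np.ndarray, np.ndarray]:
    """MODWT-scaled (scaling, wavelet) filter pair for an orthogonal basis."""
    w = pywt.Wavelet(wavelet)
    if not w.orthogonal:
        raise ValueError(f"MODWT requires an orthogonal wavelet, got {wavelet!r}")
    g = np.asarray(w.rec_lo, dtype=float)
    L = g.size
    h = np.array([(-1.0) ** l * g[L - 1 - l] for l in range(L)])
    return g / math.sqrt(2.0), h / math.sqrt(2.0)


@dataclass
class Modwt2DCoeffs:
    """Undecimated 2D wavelet coefficients.

    ``detail[j-1]`` is the level-j triplet ``(dx, dy, dd)``: wavelet filter
    along x only, along y only, and along both (diagonal).  All sub-bands
    share the input shape.
    """

    levels: int
    detail: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    smooth: np.ndarray
    wavelet: str = "haar"
    threshold: float | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.smooth.shape

    def validate(self) -> None:
        if self.levels != len(self.detail) or self.levels < 1:
            raise ValueError("levels does not match the detail pyramid")
        for j, bands in enumerate(self.detail, start=1):
            for b in bands:
                if b.shape != self.smooth.shape:
                    raise ValueError(
                        f"level-{j} sub-band shape {b.shape} != {self.smooth.shape}"
                    )


def _circ_apply(x: np.ndarray, taps: np.ndarray, step: int, axis: int,
                inverse: bool = False) -> np.ndarray:
    """Circular filtering y_t = sum_l taps[l] * x_{t -/+ l*step} along an axis."""
    sign = -1 if inverse else 1
    out = taps[0] * x
    for l in range(1, taps.size):
        out += taps[l] * np.roll(x, sign * l * step, axis=axis)
    return out


def modwt2d(grid: np.ndarray, wavelet: str = "haar", levels: int = 3) -> Modwt2DCoeffs:
    """Forward 2D MODWT of a complete (no-missing) grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("modwt2d expects a 2D grid")
    if np.isnan(grid).any():
        raise ValueError("modwt2d requires a complete grid; fill holes first")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(grid.shape) < 2 ** levels:
        raise ValueError(
            f"grid {grid.shape} too small for {levels} decomposition levels "
            f"(needs min dim >= {2 ** levels})"
        )
    g, h = modwt_filters(wavelet)
    v = grid
    detail = []
    for j in range(1, levels + 1):
        step = 1 << (j - 1)
        lo_y = _circ_apply(v, g, step, axis=0)
        hi_y = _circ_apply(v, h, step, axis=0)
        ll = _circ_apply(lo_y, g, step, axis=1)
        dx = _circ_apply(lo_y, h, step, axis=1)
        dy = _circ_apply(hi_y, g, step, axis=1)
        dd = _circ_apply(hi_y, h, step, axis=1)
        detail.append((dx, dy, dd))
        v = ll
    return Modwt2DCoeffs(levels=levels, detail=detail, smooth=v, wavelet=wavelet)


def imodwt2d(coeffs: Modwt2DCoeffs) -> np.ndarray:
    """Inverse 2D MODWT; exact up to floating tolerance on untouched coefficients."""
    coeffs.validate()
    g, h = modwt_filters(coeffs.wavelet)
    v = coeffs.smooth
    for j in range(coeffs.levels, 0, -1):
        dx, dy, dd = coeffs.detail[j - 1]
        step = 1 << (j - 1)
        lo_y = (_circ_apply(v, g, step, axis=1, inverse=True)
                + _circ_apply(dx, h, step, axis=1, inverse=True))
        hi_y = (_circ_apply(dy, g, step, axis=1, inverse=True)
                + _circ_apply(dd, h, step, axis=1, inverse=True))
        v = (_circ_apply(lo_y, g, step, axis=0, inverse=True)
             + _circ_apply(hi_y, h, step, axis=0, inverse=True))
    return v


def universal_soft_threshold(coeffs: Modwt2DCoeffs) -> Modwt2DCoeffs:
    """Soft-threshold all detail levels at lambda = sigma_hat * sqrt(2 ln N).

    sigma_hat = MAD(level-1 diagonal detail) / 0.6745; the smooth band is
    untouched.  Returns a new coefficient set (input unchanged) carrying the
    applied lambda in ``threshold``.
    """
    coeffs.validate()
    dd1 = coeffs.detail[0][2]
    mad = float(np.median(np.abs(dd1 - np.median(dd1))))
    sigma = mad / 0.6745
    n = dd1.size
    lam = sigma * math.sqrt(2.0 * math.log(n))

    def soft(w: np.ndarray) -> np.ndarray:
        return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)

    detail = [tuple(soft(b) for b in bands) for bands in coeffs.detail]
    return Modwt2DCoeffs(levels=coeffs.levels, detail=detail,
                         smooth=coeffs.smooth.copy(), wavelet=coeffs.wavelet,
                         threshold=lam)


def fill_holes(values: np.ndarray, missing_mask: np.ndarray) -> np.ndarray:
    """Fill missing cells with the average of their non-missing 8-neighbors.

    Applied iteratively — cells filled in one pass inform later passes — so
    arbitrarily large holes are filled from their frontier inward.
    Non-missing cells are returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    missing = np.asarray(missing_mask, dtype=bool).copy()
    if missing.all():
        raise ValueError("cannot fill a fully missing grid")
    out = np.where(missing, 0.0, values)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    while missing.any():
        known = ~missing
        counts = ndimage.convolve(known.astype(float), kernel, mode="constant")
        sums = ndimage.convolve(np.where(known, out, 0.0), kernel, mode="constant")
        fillable = missing & (counts > 0)
        if not fillable.any():  # unreachable for a connected grid
            raise RuntimeError("hole filling stalled")
        out[fillable] = sums[fillable] / counts[fillable]
        missing &= ~fillable
    return out


@dataclass
class QuadrantPartition:
    """Rectangular fitting regions plus the excluded central stripes.

    Each region is a half-open (row_start, row_stop, col_start, col_stop)
    span; regions are disjoint and, together with the stripe rows/columns,
    tile the grid.
    """

    shape: tuple[int, int]
    regions: list[tuple[int, int, int, int]]
    stripe_rows: tuple[int, int] | None = None
    stripe_cols: tuple[int, int] | None = None

    def region_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for r0, r1, c0, c1 in self.regions:
            m[r0:r1, c0:c1] = True
        return m

    def stripe_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if self.stripe_rows:
            m[self.stripe_rows[0]:self.stripe_rows[1], :] = True
        if self.stripe_cols:
            m[:, self.stripe_cols[0]:self.stripe_cols[1]] = True
        return m


def _find_stripe(frac: np.ndarray, n: int, threshold: float) -> tuple[int, int] | None:
    """Longest contiguous run of low-replicate lines within the middle third."""
    lo, hi = n // 3, (2 * n) // 3
    cand = frac < threshold
    best = None
    start = None
    for i in range(lo, hi + 1):
        inside = i < hi and cand[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    return best


def split_quadrants(layout: ChipLayout, stripe_frac: float = 0.05) -> QuadrantPartition:
    """Partition the chip into corner regions around the central NP stripes.

    Stripe rows (columns) are the longest contiguous run, within the middle
    third of the grid, of rows (columns) whose fraction of replicated-SNP
    cells falls below ``stripe_frac``.  With stripes on both axes the chip
    splits into 4 corners; one axis gives 2 halves; none gives the whole
    grid as a single region (logged).
    """
    rep = layout.replicated_mask()
    srows = _find_stripe(rep.mean(axis=1), layout.n_rows, stripe_frac)
    scols = _find_stripe(rep.mean(axis=0), layout.n_cols, stripe_frac)
    row_spans = ([(0, srows[0]), (srows[1], layout.n_rows)] if srows
                 else [(0, layout.n_rows)])
    col_spans = ([(0, scols[0]), (scols[1], layout.n_cols)] if scols
                 else [(0, layout.n_cols)])
    if not srows and not scols:
        logger.warning("split_quadrants: no central stripe found; "
                       "fitting a single whole-grid region")
    regions = [(r0, r1, c0, c1) for r0, r1 in row_spans for c0, c1 in col_spans
               if r1 > r0 and c1 > c0]
    return QuadrantPartition(shape=layout.shape, regions=regions,
                             stripe_rows=srows, stripe_cols=scols)


def denoise_surface(values: np.ndarray, missing_mask: np.ndarray,
                    partition: QuadrantPartition, wavelet: str = "haar",
                    levels: int = 3) -> np.ndarray:
    """Wavelet-denoise a masked grid independently on each partition region.

    Per region: fill holes, forward MODWT, universal soft threshold, inverse
    MODWT.  Stripe cells carry no estimate and are returned as 0.  If a
    region is too small for the requested level the level is clamped to
    floor(log2(min dim)) with a warning.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    for r0, r1, c0, c1 in partition.regions:
        sub = values[r0:r1, c0:c1]
        subm = np.asarray(missing_mask, dtype=bool)[r0:r1, c0:c1]
        j = min(levels, int(math.floor(math.log2(min(sub.shape)))))
        if j < 1:
            raise ValueError(f"region {(r0, r1, c0, c1)} too small to denoise")
        if j < levels:
            logger.warning("denoise_surface: region %s supports only %d levels "
                           "(requested %d)", (r0, r1, c0, c1), j, levels)
        filled = fill_holes(sub, subm)
        coeffs = universal_soft_threshold(modwt2d(filled, wavelet, j))
        out[r0:r1, c0:c1] = imodwt2d(coeffs)
    return out
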