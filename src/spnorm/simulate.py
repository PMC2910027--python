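"""Synthetic chips with known ground truth.

Generates parametric chip layouts that mimic the design facts the method
relies on — replicate groups of 3-4 probes scattered far apart, the two
alleles of each probe pair in horizontally adjacent cells, central
horizontal/vertical stripes of non-replicated probes — plus intensities
built exactly from the additive decomposition

    glog intensity = A_true + S_true + eps

so every stage of the pipeline can be tested against a known answer.

Spatial bias components model the documented artifact taxonomy: a planar
gradient (thermal/fluidic trends), Gaussian blobs (debris, droplets), and
a line scratch.  The glog offset used to back-transform the simulation
(``c_sim``) is deliberately independent of the offset the pipeline
estimates, so offset estimation is genuinely exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .glog import GlogParams, glog_transform
from .layout import (CellClass, ChipLayout, IntensityGrid, ProbesetIndex, Scale,
                     build_probeset_index)
from .normalize import NormalizationResult

__all__ = [
    "Gradient",
    "Blob",
    "Scratch",
    "SimulationConfig",
    "ChipTruth",
    "make_layout",
    "simulate_chip",
    "simulate_replicate_pair",
    "simulate_replicate_groups",
    "recovery_report",
]


@dataclass(frozen=True)
class Gradient:
    """Planar trend along x spanning -amplitude to +amplitude (glog units).

    Axis-aligned so the per-cell values are uniform on [-amplitude,
    amplitude]: the plane's extremes then sit at 2 MADs from the median and
    a smooth gradient is never mistaken for a localized artifact by the
    n=3 MAD outlier rule.
    """

    amplitude: float = 0.04


@dataclass(frozen=True)
class Blob:
    """Gaussian bump; ``center`` in fractional (y, x) or None for random."""

    height: float = 0.1
    sigma: float = 6.0
    center: tuple[float, float] | None = None


@dataclass(frozen=True)
class Scratch:
    """Line-segment artifact of given width (cells) and depth (glog units).

    ``start``/``end`` in fractional (y, x); None draws a random segment of
    length ~0.7 * min(grid dims).
    """

    depth: float = -0.5
    width: float = 3.0
    start: tuple[float, float] | None = None
    end: tuple[float, float] | None = None


def _default_bias() -> tuple:
    return (Gradient(0.04), Blob(height=0.1, sigma=6.0),
            Blob(height=-0.1, sigma=6.0), Scratch(depth=-0.5, width=3.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic chip.

    Defaults are the fixed recovery scenario used throughout the test
    suite: a 600x600 grid, 20,000 probesets in a 50/50 triplicate/
    quadruplicate mix, central NP stripes, a +/-0.04 gradient, two
    0.1-height blobs of opposite sign, one 0.5-deep scratch, and glog-scale
    noise SD 0.02 — a bias-to-noise balance whose fitted-field IQR is of
    the same order as fields observed on real chips (~(-0.03, 0.03)).
    """

    n_rows: int = 600
    n_cols: int = 600
    n_probesets: int = 20000
    replicate_weights: tuple[tuple[int, float], ...] = ((3, 0.5), (4, 0.5))
    stripe: bool = True
    stripe_width: int = 4
    bias: tuple = dc_field(default_factory=_default_bias)
    noise_sd: float = 0.02
    meanlog: float = 7.0
    sdlog: float = 0.8
    c_sim: float = 50.0
    background_meanlog: float = 6.0
    background_sdlog: float = 0.5
    seed: int = 0


@dataclass
class ChipTruth:
    """Ground truth behind one simulated chip.

    ``a_true`` is aligned with the (probeset, allele) order of
    ``build_probeset_index``; on unclipped replicated cells
    glog(raw, c_sim) - a_true - s_true == epsilon exactly.
    """

    a_true: np.ndarray
    s_true: np.ndarray
    artifact_mask: np.ndarray
    scratch_mask: np.ndarray
    epsilon: np.ndarray
    clipped_mask: np.ndarray
    c_sim: float


def _stripe_mask(config: SimulationConfig) -> np.ndarray:
    m = np.zeros((config.n_rows, config.n_cols), dtype=bool)
    if config.stripe:
        w = config.stripe_width
        r0 = config.n_rows // 2 - w // 2
        c0 = config.n_cols // 2 - w // 2
        m[r0:r0 + w, :] = True
        m[:, c0:c0 + w] = True
    return m


def make_layout(config: SimulationConfig) -> ChipLayout:
    """Random feasible layout: adjacent allele pairs, distant replicates.

    The members of each probe pair occupy horizontally adjacent cells; the
    3-4 pairs of a probeset are placed with pairwise separation of at least
    one tenth of the grid diagonal, falling back to any free pair after
    bounded retries.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    nr, nc = config.n_rows, config.n_cols
    stripe = _stripe_mask(config)
    reps_choices = np.array([r for r, _ in config.replicate_weights])
    reps_p = np.array([p for _, p in config.replicate_weights], dtype=float)
    reps_p /= reps_p.sum()
    reps = rng.choice(reps_choices, size=config.n_probesets, p=reps_p)
    needed = int(reps.sum()) * 2
    available = int((~stripe).sum())
    if needed > 0.85 * available:
        raise ValueError(
            f"infeasible packing: {needed} probe cells requested on "
            f"{available} available cells"
        )
    min_sep2 = (math.hypot(nr, nc) / 10.0) ** 2
    occupied = stripe.copy()
    cell_class = np.where(stripe, np.int8(CellClass.NONREPLICATED),
                          np.int8(CellClass.EMPTY))
    probeset_id = np.full((nr, nc), None, dtype=object)
    allele = np.full((nr, nc), None, dtype=object)
    batch = 64
    for p in range(config.n_probesets):
        pid = f"PS{p:05d}"
        chosen: list[tuple[int, int]] = []
        cand_y = rng.integers(0, nr, size=batch)
        cand_x = rng.integers(0, nc - 1, size=batch)
        idx = 0
        for _k in range(int(reps[p])):
            tries = 0
            while True:
                if idx >= batch:
                    cand_y = rng.integers(0, nr, size=batch)
                    cand_x = rng.integers(0, nc - 1, size=batch)
                    idx = 0
                y, x = int(cand_y[idx]), int(cand_x[idx])
                idx += 1
                tries += 1
                if tries > 4000:
                    raise ValueError("infeasible packing: placement retries exhausted")
                if occupied[y, x] or occupied[y, x + 1]:
                    continue
                if tries <= 40 and any((y - cy) ** 2 + (x - cx) ** 2 < min_sep2
                                       for cy, cx in chosen):
                    continue  # best-effort distant placement
                break
            chosen.append((y, x))
            occupied[y, x] = occupied[y, x + 1] = True
            cell_class[y, x] = cell_class[y, x + 1] = CellClass.REPLICATED_SNP
            probeset_id[y, x] = probeset_id[y, x + 1] = pid
            allele[y, x] = "A"
            allele[y, x + 1] = "B"
    # sprinkle a few control cells on remaining free positions
    free_y, free_x = np.nonzero(~occupied)
    n_ctrl = min(free_y.size, max(4, (nr * nc) // 500))
    if n_ctrl:
        pick = rng.choice(free_y.size, size=n_ctrl, replace=False)
        cell_class[free_y[pick], free_x[pick]] = CellClass.CONTROL
    return ChipLayout(nr, nc, cell_class, probeset_id, allele)


def _segment_distance(yy: np.ndarray, xx: np.ndarray, p0, p1) -> np.ndarray:
    """Distance from every grid cell to the segment p0-p1 (grid units)."""
    y0, x0 = p0
    y1, x1 = p1
    dy, dx = y1 - y0, x1 - x0
    denom = dy * dy + dx * dx
    t = ((yy - y0) * dy + (xx - x0) * dx) / denom if denom > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (y0 + t * dy), xx - (x0 + t * dx))


def _bias_surfaces(config: SimulationConfig, rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(smooth bias, artifact bias, scratch mask); artifacts = blobs + scratches."""
    nr, nc = config.n_rows, config.n_cols
    yy, xx = np.mgrid[0:nr, 0:nc].astype(float)
    smooth = np.zeros((nr, nc))
    artifact = np.zeros((nr, nc))
    scratch_mask = np.zeros((nr, nc), dtype=bool)
    for comp in config.bias:
        if isinstance(comp, Gradient):
            xn = xx / max(nc - 1, 1)
            smooth += comp.amplitude * (2.0 * xn - 1.0)
        elif isinstance(comp, Blob):
            if comp.center is None:
                cy, cx = rng.uniform(0.1, 0.9, size=2)
            else:
                cy, cx = comp.center
            cy, cx = cy * (nr - 1), cx * (nc - 1)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            artifact += comp.height * np.exp(-d2 / (2.0 * comp.sigma ** 2))
        elif isinstance(comp, Scratch):
            if comp.start is None or comp.end is None:
                length = 0.7 * min(nr, nc)
                theta = rng.uniform(0, math.pi)
                cy = rng.uniform(0.3, 0.7) * (nr - 1)
                cx = rng.uniform(0.3, 0.7) * (nc - 1)
                hy, hx = (length / 2) * math.sin(theta), (length / 2) * math.cos(theta)
                p0 = (np.clip(cy - hy, 0, nr - 1), np.clip(cx - hx, 0, nc - 1))
                p1 = (np.clip(cy + hy, 0, nr - 1), np.clip(cx + hx, 0, nc - 1))
            else:
                p0 = (comp.start[0] * (nr - 1), comp.start[1] * (nc - 1))
                p1 = (comp.end[0] * (nr - 1), comp.end[1] * (nc - 1))
            dist = _segment_distance(yy, xx, p0, p1)
            under = dist <= comp.width / 2.0
            artifact += np.where(under, comp.depth, 0.0)
            scratch_mask |= under
        else:
            raise TypeError(f"unknown bias component {comp!r}")
    return smooth, artifact, scratch_mask


def simulate_chip(layout: ChipLayout, config: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  a_true: np.ndarray | None = None,
                  index: ProbesetIndex | None = None,
                  ) -> tuple[IntensityGrid, ChipTruth]:
    """Raw-scale intensities built from A_true + S_true + eps on replicated cells.

    Allelic signals are drawn log-normal on the raw scale (then glog
    transformed with ``c_sim``); non-replicated cells receive independent
    background draws.  The artifact mask marks cells whose blob/scratch
    contribution exceeds the 3 * noise_sd detectability floor.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    if index is None:
        index = build_probeset_index(layout)
    params = GlogParams(config.c_sim)
    if a_true is None:
        raw_a = rng.lognormal(config.meanlog, config.sdlog, size=index.n_groups)
        a_true = np.asarray(glog_transform(raw_a, params))
    smooth, artifact, scratch_mask = _bias_surfaces(config, rng)
    s_true = smooth + artifact
    eps = rng.normal(0.0, config.noise_sd, size=layout.shape) if config.noise_sd > 0 \
        else np.zeros(layout.shape)
    values = rng.lognormal(config.background_meanlog, config.background_sdlog,
                           size=layout.shape)
    y_rep = a_true[index.group_of] + s_true[index.rows, index.cols] \
        + eps[index.rows, index.cols]
    c = config.c_sim
    raw_rep = (np.exp(y_rep) - c * c * np.exp(-y_rep)) / 2.0
    clipped = np.zeros(layout.shape, dtype=bool)
    clipped[index.rows, index.cols] = raw_rep < 0
    values[index.rows, index.cols] = np.maximum(raw_rep, 0.0)
    floor = 3.0 * config.noise_sd if config.noise_sd > 0 else 0.0
    artifact_mask = np.abs(artifact) > floor
    grid = IntensityGrid(values, Scale.RAW, np.zeros(layout.shape, dtype=bool))
    truth = ChipTruth(a_true=a_true, s_true=s_true, artifact_mask=artifact_mask,
                      scratch_mask=scratch_mask, epsilon=eps, clipped_mask=clipped,
                      c_sim=c)
    return grid, truth


def simulate_replicate_pair(config: SimulationConfig,
                            ) -> tuple[ChipLayout, list[tuple[IntensityGrid, ChipTruth]]]:
    """Two chips sharing the layout and allelic signals but with independent
    bias fields and noise — the replicate-hybridization setting used to
    measure reproducibility."""
    layout = make_layout(config)
    index = build_probeset_index(layout)
    rng_a = np.random.default_rng([config.seed, 2])
    raw_a = rng_a.lognormal(config.meanlog, config.sdlog, size=index.n_groups)
    a_true = np.asarray(glog_transform(raw_a, GlogParams(config.c_sim)))
    chips = []
    for k in (3, 4):
        rng = np.random.default_rng([config.seed, k])
        chips.append(simulate_chip(layout, config, rng=rng, a_true=a_true,
                                   index=index))
    return layout, chips


def simulate_replicate_groups(n_groups: int, replicates: int = 3,
                              meanlog: float = 7.0, sdlog: float = 1.0,
                              cv_mult: float = 0.15, sd_add: float = 200.0,
                              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Replicate groups under a two-component (additive + multiplicative)
    raw-scale error model: x = mu * exp(eta) + delta, clipped at 0.

    Returns (values, group codes) in the flat layout the glog criterion
    consumes.  The classic setting where the raw spread grows with the mean,
    the plain log over-stabilizes near zero, and glog flattens both.
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(meanlog, sdlog, size=n_groups)
    group_of = np.repeat(np.arange(n_groups), replicates)
    eta = rng.normal(0.0, cv_mult, size=group_of.size)
    delta = rng.normal(0.0, sd_add, size=group_of.size) if sd_add > 0 else 0.0
    x = np.maximum(mu[group_of] * np.exp(eta) + delta, 0.0)
    return x, group_of


def recovery_report(result: NormalizationResult, truth: ChipTruth,
                    match_radius: int = 4) -> dict[str, float]:
    """Parameter-recovery metrics of a normalization run against ground truth.

    corr(S_hat, S_true) is Pearson on covered cells (shift-invariant, so
    unaffected by the A/S identifiability constant); RMSE of the allelic
    estimates is reported for the final estimates and for the
    median-of-raw-replicates initialization ("before").  Outlier precision/
    recall versus the artifact mask allow a Chebyshev ``match_radius``
    (default 4 = half the level-3 Haar filter support, the denoiser's
    localization limit); the exact-pixel counterparts are also reported.
    """
    cov = result.field.covered_mask
    s_hat = result.field.value[cov]
    s_true = truth.s_true[cov]
    if np.ptp(s_true) == 0 or np.ptp(s_hat) == 0:
        corr = float("nan")  # no injected (or fitted) spatial structure
    else:
        corr = float(np.corrcoef(s_hat, s_true)[0, 1])
    out: dict[str, float] = {
        "corr_s": corr,
        "rmse_a_after": float(np.sqrt(np.mean(
            (result.allelic.values - truth.a_true) ** 2))),
    }
    if result.initial_allelic is not None:
        out["rmse_a_before"] = float(np.sqrt(np.mean(
            (result.initial_allelic.values - truth.a_true) ** 2)))
    if result.outliers is not None:
        flags = result.outliers.flags & cov
        mask = truth.artifact_mask & cov
        size = 2 * match_radius + 1
        dil_mask = ndimage.binary_dilation(truth.artifact_mask,
                                           np.ones((size, size), bool))
        dil_flag = ndimage.binary_dilation(result.outliers.flags,
                                           np.ones((size, size), bool))
        nf, nm = int(flags.sum()), int(mask.sum())
        out["outlier_precision"] = float((flags & dil_mask).sum() / nf) if nf else float("nan")
        out["outlier_recall"] = float((mask & dil_flag).sum() / nm) if nm else float("nan")
        out["outlier_precision_exact"] = float((flags & mask).sum() / nf) if nf else float("nan")
        out["outlier_recall_exact"] = float((mask & flags).sum() / nm) if nm else float("nan")
        scratch = truth.scratch_mask & cov
        ns = int(scratch.sum())
        out["scratch_recall"] = float((scratch & dil_flag).sum() / ns) if ns else float("nan")
    return out
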