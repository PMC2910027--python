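# Methods

## The decomposition model

Replicate-probe SNP arrays place 3–4 identical probes per SNP allele at
mutually distant chip positions, with the two alleles of each probe pair in
adjacent cells. Any systematic disagreement among replicates of one allele
must therefore come from location-dependent effects. On the glog scale we
model each replicated cell as

    I_xy = A_jk + S_xy + eps_xy

where `A_jk` is the allelic signal (specific plus nonspecific
hybridization), `S_xy` the chip-specific spatial bias, and `eps_xy`
zero-mean, spatially uncorrelated noise. The model is not identifiable in
the absolute level — `(A + c) + (S − c)` fits equally well — and no
constraint is imposed: a global intensity shift is absorbed by the quantile
scaling of downstream genotype callers. Users comparing `S` across chips
should therefore read it up to an additive constant; the reproducibility
metric (Pearson-based R²) and the outlier rule (median-centered) are both
shift-invariant by construction.

Assumptions worth stating: replicates are strict technical duplicates
(identical sequence, hence identical hybridization affinity); the bias
field affects nearby probes similarly; and the noise is symmetric around
zero after variance stabilization. Non-replicated probes (copy-number
probes, QC probes) carry no replicate information and are excluded from
estimation; their cells pass through the pipeline unchanged.

## Variance stabilization

Raw intensities carry additive background noise plus multiplicative
hybridization noise, so the replicate spread grows with the signal and a
least-squares surface fit would be dominated by bright probes. The
generalized logarithm `g(x) = ln(x + sqrt(x^2 + c^2))` interpolates between
`ln(2x)` at high intensity and a linear scale near zero. The offset `c`
(raw-intensity units, default: estimated per chip) is chosen to minimize
the absolute Spearman correlation between per-replicate-group SD and mean
on the transformed scale — directly the property the transform exists to
deliver. The estimator samples up to 50,000 replicate groups uniformly
without replacement (seeded, default seed 0; all groups if fewer exist),
scans 33 log-spaced candidates on [1e-2, 10·max intensity], and refines by
bounded 1-D minimization. The rank-based criterion needs no parametric
error-model fit; it is isolated behind `replicate_sd_mean_rho` so a
moment-based estimator could be swapped in without touching callers.
Estimation is per chip, consistent with the single-chip design of the whole
procedure. With fewer than 10 usable groups the criterion is undefined and
estimation refuses.

## Surface fitting

`S` is fitted to the residuals `I − A_hat` by a two-dimensional
maximal-overlap discrete wavelet transform (MODWT): undecimated, defined
for arbitrary grid sizes, and shift-invariant (the x–y origin of a chip is
arbitrary). The transform is implemented separably — scaling/wavelet filter
pairs applied along rows then columns per level, upsampled by 2^(j−1) at
level j, with circular boundary handling — using the orthogonal filter
coefficients from PyWavelets (`rec_lo`, with the quadrature-mirror wavelet
filter) rescaled by 1/sqrt(2). Unmodified coefficients invert exactly
(tested to 1e-8) and conserve energy (1e-6 relative).

Defaults follow the setting that maximized cross-chip reproducibility on
replicate hybridizations: Haar basis, decomposition level J = 3, universal
soft threshold, one iteration. Thresholding uses
`lambda = sigma_hat * sqrt(2 ln N)` with N the region's cell count and
`sigma_hat = MAD(level-1 diagonal detail)/0.6745` — the standard
Donoho–Johnstone noise proxy, computed per region; all detail levels 1..J
are thresholded and the smooth band is untouched. The Haar choice keeps
sharp artifact edges; a deep scratch therefore survives thresholding while
white noise is almost entirely removed.

Holes (non-replicated cells) are filled before the transform with the
average of their non-missing 8-neighbors, iteratively, so large holes fill
frontier-inward. The central horizontal/vertical stripes of non-replicated
probes are too broad to interpolate across; instead the surface is fitted
independently to the four corner regions. Stripes are detected as the
longest contiguous run, within the middle third of each axis, of lines
whose replicated-cell fraction falls below `stripe_frac` (default 0.05 —
low enough that no probeset-bearing line qualifies, high enough to catch
stripes containing stray control cells). A stripe on one axis only yields
two half-regions; none yields a single whole-grid region (logged). Stripe
cells receive bias 0 — no replicated probe informs them and corrected
output must never contain missing intensities. If a region cannot support
the requested J the level is clamped to `floor(log2(min dim))` with a
warning.

## Iteration and outlier handling

A_jk is initialized with the replicate median (robust: the scattered
replicates are rarely all under one artifact) and, once the fitted surface
has absorbed the spatial disturbance, updated with the replicate mean of
`I − S_hat`, the efficient estimator at n = 3–4. The surface-fit/mean-update
pair can be iterated (`iterations`, default 1); per-iteration field
summaries and the max-abs change in A_hat are logged so convergence can be
judged. On simulated chips the cross-chip reproducibility gain of a second
iteration is under 3% of the first iteration's gain; individual probesets
with a majority of replicates under a deep artifact do keep moving at
iteration 2 (their median initialization was contaminated), which is why
the change is monitored per group rather than assumed uniformly small.

Outlier flagging (off by default, matching a workflow whose downstream
caller cannot accept missing intensities): cells with
`|S_hat − median(S_hat)| > n_mad * MAD(S_hat)` over covered cells are
flagged (default n = 3, selected on reproducibility grounds), then one
refinement pass over the covered 8-neighborhood: flagged cells with no
flagged neighbor are reinstated (isolated aberrations are likelier
estimation noise than debris), and unflagged cells with ≥ 50% flagged
neighbors are flagged. Order — primary, reinstate, densify, one pass each —
is a fixed design choice. A degenerate field (MAD = 0) flags nothing, with
a warning. Revision recomputes group means without flagged probes; a group
whose replicates are all flagged keeps its unrevised estimate and is
reported, never dropped — losing probes in one region does not eliminate a
SNP whose other replicates are elsewhere. Corrected intensities are always
emitted for every replicated cell.

## Synthetic chips

The generator emulates the layout facts the method relies on (replicate
groups of 3 or 4, 50/50 by default; allele pairs horizontally adjacent;
pairs of a probeset kept at least one tenth of the grid diagonal apart,
best-effort with bounded rejection sampling; central NP stripes) and builds
intensities exactly as `glog_inverse(A + S + eps, c_sim)`, so
`glog(raw, c_sim) − A − S == eps` on replicated cells by construction.
Default study conditions (the scenario all full-scale tests use): 600×600
grid, 20,000 probesets, stripes of width 4, bias = axis-aligned planar
gradient of amplitude ±0.04 + two Gaussian blobs of height ±0.1 (sigma 6
cells) + one scratch of depth −0.5 (width 3, length 0.7·grid, random
placement), glog-scale noise SD 0.02, allelic signals log-normal
(meanlog 7.0, sdlog 0.8 — median ~1100 raw units and an IQR ratio like
real chips), `c_sim` = 50, independent log-normal background on
non-replicated cells. The gradient is axis-aligned so its value
distribution is uniform and its extremes sit at 2 MADs — a smooth trend
should not trip a 3-MAD artifact rule by its tail shape alone. The
resulting fitted-field IQR (about ±0.015 at these settings) is of the same
order as fields observed on real chips. `c_sim` is deliberately different
from anything the pipeline assumes, so offset estimation is genuinely
exercised. Rare cells where `A + S + eps < ln(c_sim)` would invert to a
negative intensity are clipped to 0 and recorded in `clipped_mask`.

What the generator does **not** emulate: probe-sequence effects, genotype
cluster structure (the two alleles of a SNP are drawn independently),
cross-hybridization, or saturation. Passing the recovery suite therefore
shows the estimator recovers the model's own decomposition under realistic
magnitudes — not that any particular genotype caller will improve on a
given real dataset.

The artifact mask marks cells whose blob/scratch component exceeds
3·noise_sd (a detectability floor); the scratch support is kept separately.
Recovery metrics: Pearson correlation of fitted vs injected field on
covered cells (shift-invariant, so unaffected by the identifiability
constant); RMSE of the allelic estimates against truth, for the final
estimates and the median initialization; and outlier precision/recall with
a Chebyshev match radius of 4 cells (half the level-3 Haar filter support —
a level-3 surface cannot localize a 3-pixel scratch to the pixel, and
exact-pixel counts, also reported, would measure the denoiser's resolution
rather than detection). Recall is additionally reported on scratch cells
alone: blob-ring cells whose total bias happens to cancel against the
gradient are in the artifact mask but invisible to any field-based rule.

## Numerical notes

- Group medians use the standard middle / mean-of-two-middles convention;
  group reductions are vectorized via bincount on a flat replicate index
  sorted by (probeset, allele) — the deterministic iteration order.
- The pipeline is fully deterministic given the glog seed; reruns are
  bitwise identical.
- `pairwise_R2` computes `(lambda_1 − 1)^2` with `lambda_1 = 1 + |r|` the
  major eigenvalue of the 2×2 correlation matrix — equal to the squared
  Pearson correlation and to the Deming-regression R² on standardized
  pairs; `deming_major_eigenvalue` is exposed separately in case an
  alternative monotone transform of `lambda_1` is ever preferred.
- `mcnemar_one_tailed` uses the exact binomial tail up to
  n = 1e5 discordant pairs, then a continuity-corrected normal
  approximation; extremely lopsided pairs underflow to 0.0 in double
  precision, which is reported as computed.
- Text CEL v3 writes intensities at 6 significant digits (documented
  round-trip precision); TSV uses `%.17g` and round-trip float parsing, so
  values survive bit-for-bit; the `.npz` container stores a NaN payload
  plus an explicit missing mask to avoid NaN-semantics ambiguity. Binary
  GCOS/Calvin CEL files are rejected with an explicit "unsupported CEL
  dialect" error. The probe-map TSV is the single source of truth for cell
  classes; converting vendor library files into it is an extension point,
  not a feature.

## Problem sizes used by the test suite

Unit tests run on 48–200 cell grids with proportionally scaled probeset
counts; the full-scale recovery suite runs the default 600×600 scenario on
seeds 10–19 plus a replicate-chip pair — the scale at which stripe
geometry, quadrant fitting and the 3-MAD rule behave as on real chips while
the whole suite stays fast.

## Known limitations

- Bias is estimated (and corrected) only on replicated SNP cells; extending
  `S` to non-replicated (copy-number) probes would need interpolation
  across the stripes, e.g. a 2D loess, and is out of scope.
- The stripe detector assumes central stripes; decorative or off-center
  layouts fall back to fewer regions.
- Only orthogonal wavelet bases with circular boundary handling are
  supported (Haar default); decimated transforms and cycle-spinning are
  non-goals.
- The c-estimation criterion is rank-based and robust but can sit on a flat
  valley: any c in the valley stabilizes equally well, so the exact value
  is not meaningful on its own.
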