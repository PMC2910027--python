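# spnorm — single-chip spatial bias removal for replicate-probe SNP arrays

High-density SNP genotyping arrays (Affymetrix SNP 6.0 and platforms with a
similar design) suffer chip-specific, spatially structured intensity
artifacts: temperature gradients and uneven washing produce subtle smooth
trends, while debris, droplets and scratches corrupt localized regions
outright. Because each SNP allele is interrogated by only 3–4 replicate
probes, these biases inflate failed-call rates and genotyping errors.
`spnorm` removes them one chip at a time, before any genotype caller runs,
by exploiting two design facts: the replicate probes of an allele are strict
technical duplicates, and they are scattered far apart on the chip.

## Model and procedure

On the generalized-log (glog) scale, the intensity of the replicated probe
at cell (x, y) interrogating SNP j, allele k is decomposed as

    I_xy = A_jk + S_xy + eps_xy

with A_jk the allelic signal shared by the replicates, S_xy a smooth-or-
locally-sharp spatial bias field, and eps_xy spatially uncorrelated noise
(A and S are identified only up to an additive constant, which downstream
callers are invariant to). The estimation pipeline:

1. **glog transform** `g(x) = ln(x + sqrt(x^2 + c^2))`, with `c` estimated
   from up to 50,000 replicate groups so that replicate spread becomes
   independent of replicate level;
2. **initialize** each A_jk with the replicate **median** (robust to
   localized artifacts);
3. **fit S_xy** by a 2D maximal-overlap discrete wavelet transform (Haar,
   3 levels, universal soft threshold) on the residuals I_xy − A_jk,
   independently on the four chip corners separated by the central stripes
   of non-replicated probes; non-replicated cells are holes filled by
   iterative neighbor averaging;
4. **update** A_jk with the replicate **mean** of I_xy − S_xy (efficient
   once the spatial term is absorbed); optionally iterate 3–4 — one pass
   captures essentially all of the reproducibility gain;
5. optionally **flag outliers** (|S_xy − median| > 3 MAD plus an
   8-neighborhood refinement) and revise A_jk without them;
6. **write back** glog-inverse-transformed A_jk to the replicated cells;
   all other cells pass through unchanged.

Evaluation utilities cover cross-chip reproducibility R² (via the major
eigenvalue of the pairwise correlation matrix, the Deming-regression
coefficient of determination), genotype concordance tables, call rates,
Mendelian-trio consistency, and one-tailed McNemar tests. A synthetic
module generates chips with known layout, allelic signal, bias field and
artifacts so every stage is testable without any array data.

## Worked example

`examples/correct_one_chip.py` simulates a 200×200 chip (2,200 probesets;
±0.04 gradient, two 0.1-height blobs, one 0.5-deep scratch, noise SD 0.02
on the glog scale) and corrects it:

```
estimated glog offset c = 64.3 (simulation used 50.0)
fitted bias field: median -0.0018, IQR (-0.0156, 0.0146)
corr(S_hat, S_true)          = 0.984
RMSE of allelic estimates    = 0.0142 after vs 0.0206 for the raw-replicate median
artifact flagging (n=3 MAD)  : precision 0.99, scratch recall 1.00
```

The fitted field tracks the injected bias (r = 0.98), the corrected
allelic estimates are ~30% closer to truth than the uncorrected replicate
medians, and the scratch is fully recovered by the outlier rule. The other
examples show the glog variance-stabilization rationale
(`glog_stabilization.py`), bias-field diagnostic maps (`bias_field_map.py`),
and the genotype-level metrics (`genotype_evaluation.py`).

A thin CLI wraps the same functions:

```sh
spnorm simulate --rows 200 --cols 200 --probesets 2200 --seed 1 --out-prefix chip
spnorm run --input chip.tsv --layout chip.map.tsv --out corrected.tsv --report report.json
spnorm field --input chip.tsv --layout chip.map.tsv --out-png field.png
spnorm eval mcnemar 16887 7690
```

Intensities are read from text CEL v3 files, plain TSV matrices, or a
portable `.npz` container; probe maps are TSV
(`x y class probeset_id allele`).

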