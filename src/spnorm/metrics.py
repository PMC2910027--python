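"""Evaluation metrics for genotyping normalization.

Covers the downstream quantities used to judge a spatial correction:
cross-chip reproducibility of the allelic estimates (Deming R^2 via the
major eigenvalue of the pairwise correlation matrix), genotype concordance
tables and call rates against a consensus truth set, Mendelian-trio
consistency, and one-tailed McNemar tests on discordant-pair counts.

Genotype codes count one designated allele: 0/1/2 copies, with -1 (``NA``
in TSV) for a failed call.  Which allele is counted is irrelevant to every
metric here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MISSING",
    "GenotypeTable",
    "TrioSet",
    "ConcordanceTable",
    "MendelStatus",
    "pairwise_R2",
    "deming_major_eigenvalue",
    "concordance_table",
    "call_rate",
    "mendel_check",
    "mendel_rates",
    "mendel_rates_from_counts",
    "mcnemar_one_tailed",
]

MISSING = -1
_VALID_CODES = frozenset({-1, 0, 1, 2})

#: Gametes a parent of each genotype can transmit (count of the coded allele).
_TRANSMIT = {0: (0,), 1: (0, 1), 2: (1,)}

_CONSISTENT = np.zeros((3, 3, 3), dtype=bool)
for _f in range(3):
    for _m in range(3):
        for _a in _TRANSMIT[_f]:
            for _b in _TRANSMIT[_m]:
                _CONSISTENT[_f, _m, _a + _b] = True


class MendelStatus(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    MISSING = "missing"


@dataclass
class GenotypeTable:
    """Sample x SNP call matrix with codes {0, 1, 2, MISSING}."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        bad = set(np.unique(vals)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        self.calls = self.calls.astype(np.int8)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeTable":
        """Rows = samples, columns = SNPs, cells 0/1/2/NA."""
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False)
        return cls(df.fillna(MISSING).astype(np.int8))

    def write_tsv(self, path: str | Path) -> None:
        out = self.calls.astype(object).where(self.calls != MISSING, "NA")
        out.to_csv(path, sep="\t")


@dataclass
class TrioSet:
    """Father/mother/offspring sample-identifier triples."""

    trios: list[tuple[str, str, str]]

    def validate_against(self, table: GenotypeTable) -> None:
        known = set(table.samples)
        for trio in self.trios:
            for sid in trio:
                if sid not in known:
                    raise ValueError(f"trio sample {sid!r} absent from the call table")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TrioSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("father", "mother", "child"):
            if col not in df.columns:
                raise ValueError("trio TSV needs columns father, mother, child")
        return cls([tuple(r) for r in df[["father", "mother", "child"]].to_numpy()])


_CODE_LABELS = ("0", "1", "2", "Missing")


@dataclass
class ConcordanceTable:
    """4x4 truth-code x called-code counts (order 0, 1, 2, Missing)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise ValueError("ConcordanceTable needs a non-negative 4x4 count matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        """Counts, or percentages of the grand total to 1 decimal."""
        if percent:
            data = np.round(100.0 * self.counts / self.total, 1)
        else:
            data = self.counts
        return pd.DataFrame(data, index=list(_CODE_LABELS), columns=list(_CODE_LABELS))


def deming_major_eigenvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Major eigenvalue lambda_1 = 1 + |r| of the 2x2 pairwise correlation matrix."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 + abs(r)


def pairwise_R2(a: np.ndarray, b: np.ndarray) -> float:
    """Reproducibility R^2 = (lambda_1 - 1)^2 of two paired estimate vectors.

    Equals the coefficient of determination of an errors-in-both-variables
    (Deming) fit on standardized pairs, i.e. the squared Pearson
    correlation; higher is more reproducible.  Sign-insensitive by the
    eigenvalue construction.
    """
    lam1 = deming_major_eigenvalue(a, b)
    return (lam1 - 1.0) ** 2


def _code_index(arr: np.ndarray) -> np.ndarray:
    idx = np.where(arr == MISSING, 3, arr)
    return idx.astype(np.int64)


def concordance_table(truth: GenotypeTable, called: GenotypeTable,
                      samples: list[str] | None = None,
                      snps: list[str] | None = None) -> ConcordanceTable:
    """Cross-tabulate truth x called codes over an optional sample/SNP subset."""
    t = truth.calls
    c = called.calls
    if samples is not None:
        t, c = t.loc[samples], c.loc[samples]
    else:
        if list(t.index) != list(c.index):
            raise ValueError("sample sets differ between truth and called tables")
    if snps is not None:
        t, c = t[snps], c[snps]
    elif list(t.columns) != list(c.columns):
        raise ValueError("SNP sets differ between truth and called tables")
    if t.shape != c.shape:
        raise ValueError("table shapes differ")
    ti = _code_index(t.to_numpy().ravel())
    ci = _code_index(c.to_numpy().ravel())
    counts = np.bincount(4 * ti + ci, minlength=16).reshape(4, 4)
    return ConcordanceTable(counts)


def call_rate(table: ConcordanceTable, denominator: str = "all") -> float:
    """Percentage of genotypes with a non-missing call.

    ``denominator="all"`` uses every genotype in the table;
    ``"nonmissing_truth"`` restricts to genotypes whose truth code is
    non-missing.
    """
    counts = table.counts
    called = counts[:, :3]
    if denominator == "all":
        denom = counts.sum()
        num = called.sum()
    elif denominator == "nonmissing_truth":
        denom = counts[:3].sum()
        num = called[:3].sum()
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("empty denominator")
    return 100.0 * num / denom


def mendel_check(father: int, mother: int, child: int) -> MendelStatus:
    """Mendelian-transmission check of one trio genotype.

    MISSING if any call failed; else CONSISTENT iff the child genotype can
    be formed by drawing one allele from each parent (e.g. two homozygous
    0 parents admit only a 0 child; parents 0 and 2 admit only 1).
    Symmetric in the parents.
    """
    for code in (father, mother, child):
        if code not in _VALID_CODES:
            raise ValueError(f"invalid genotype code {code!r}")
    if MISSING in (father, mother, child):
        return MendelStatus.MISSING
    return (MendelStatus.CONSISTENT if _CONSISTENT[father, mother, child]
            else MendelStatus.INCONSISTENT)


def mendel_rates(trios: TrioSet, calls: GenotypeTable) -> dict[str, float]:
    """Trio availability and Mendelian-inconsistency percentages.

    availability = % of trio-SNPs with all three calls present;
    inconsistency = % of available trio-SNPs violating Mendelian
    transmission.
    """
    trios.validate_against(calls)
    vals = calls.calls
    n_consistent = n_inconsistent = 0
    total = len(trios.trios) * vals.shape[1]
    for f, m, c in trios.trios:
        fa = vals.loc[f].to_numpy()
        mo = vals.loc[m].to_numpy()
        ch = vals.loc[c].to_numpy()
        ok = (fa != MISSING) & (mo != MISSING) & (ch != MISSING)
        cons = _CONSISTENT[fa[ok], mo[ok], ch[ok]]
        n_consistent += int(cons.sum())
        n_inconsistent += int((~cons).sum())
    return mendel_rates_from_counts(n_consistent, n_inconsistent, total)


def mendel_rates_from_counts(n_consistent: int, n_inconsistent: int,
                             total: int) -> dict[str, float]:
    """Rates from aggregate trio-SNP counts (same arithmetic as mendel_rates)."""
    available = n_consistent + n_inconsistent
    if available == 0:
        raise ValueError("no trio-SNPs available for comparison")
    return {
        "available_fraction": 100.0 * available / total,
        "inconsistency_rate": 100.0 * n_inconsistent / available,
        "n_consistent": n_consistent,
        "n_inconsistent": n_inconsistent,
        "total": total,
    }


#: above this discordant-pair total the exact binomial tail is replaced by a
#: continuity-corrected normal approximation.
_MCNEMAR_EXACT_LIMIT = 100_000


def mcnemar_one_tailed(n_better: int, n_worse: int) -> float:
    """Exact one-tailed McNemar p-value P(X >= n_better | n, 1/2).

    Tests whether calls move to the better category more often than chance
    among the n = n_better + n_worse discordant pairs.  Exact binomial tail
    up to n = 1e5, then a continuity-corrected normal approximation.
    """
    if n_better < 0 or n_worse < 0:
        raise ValueError("discordant-pair counts must be non-negative")
    n = n_better + n_worse
    if n < 1:
        raise ValueError("at least one discordant pair required")
    if n <= _MCNEMAR_EXACT_LIMIT:
        return float(stats.binom.sf(n_better - 1, n, 0.5))
    z = (n_better - 0.5 - n / 2.0) / np.sqrt(n / 4.0)
    return float(stats.norm.sf(z))
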