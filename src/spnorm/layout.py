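"""Chip geometry, probe classes, and layout/intensity file I/O.

The array is modelled as an ``n_rows x n_cols`` grid of cells.  Coordinates
are 0-based with ``x`` indexing columns and ``y`` indexing rows; all grids
are stored row-major and indexed ``[y, x]``.  Each cell carries a class:

* ``REPLICATED_SNP`` — member of a replicate group (3–4 identical probes
  per SNP allele, scattered over the chip); these are the only cells the
  spatial normalization uses.
* ``NONREPLICATED``  — non-polymorphic (copy-number) probes, unreplicated.
* ``CONTROL``        — alignment / QC probes.
* ``EMPTY``          — no probe.

Supported intensity containers: a text CEL (version 3) dialect, a plain TSV
matrix (missing cells serialized as ``NA``), and a portable ``.npz`` matrix
(NaN payload plus an explicit boolean mask).  Binary GCOS/Calvin CEL files
are out of scope and rejected with an explicit error.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CellClass",
    "Scale",
    "ChipLayout",
    "IntensityGrid",
    "ProbesetIndex",
    "load_layout",
    "write_layout",
    "load_intensities",
    "write_intensities",
    "build_probeset_index",
]


class CellClass(enum.IntEnum):
    EMPTY = 0
    REPLICATED_SNP = 1
    NONREPLICATED = 2
    CONTROL = 3


class Scale(enum.Enum):
    RAW = "raw"
    GLOG = "glog"


_CLASS_FROM_TSV = {
    "snp_rep": CellClass.REPLICATED_SNP,
    "np": CellClass.NONREPLICATED,
    "control": CellClass.CONTROL,
    "empty": CellClass.EMPTY,
}
_CLASS_TO_TSV = {v: k for k, v in _CLASS_FROM_TSV.items()}


@dataclass
class ChipLayout:
    """Grid geometry plus the per-cell probe classification.

    ``probeset_id`` and ``allele`` are object arrays holding strings on
    REPLICATED_SNP cells and ``None`` everywhere else.
    """

    n_rows: int
    n_cols: int
    cell_class: np.ndarray
    probeset_id: np.ndarray
    allele: np.ndarray

    def __post_init__(self) -> None:
        self.cell_class = np.asarray(self.cell_class, dtype=np.int8)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def replicated_mask(self) -> np.ndarray:
        return self.cell_class == CellClass.REPLICATED_SNP

    def validate(self) -> None:
        shape = (self.n_rows, self.n_cols)
        for name in ("cell_class", "probeset_id", "allele"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        rep = self.replicated_mask()
        pid = self.probeset_id[rep]
        alle = self.allele[rep]
        if any(p is None for p in pid.ravel()):
            raise ValueError("REPLICATED_SNP cell without a probeset_id")
        bad = ~np.isin(alle.astype(object), np.array(["A", "B"], dtype=object))
        if bad.any():
            raise ValueError("REPLICATED_SNP cell with allele not in {A, B}")
        if any(p is not None for p in self.probeset_id[~rep].ravel()):
            raise ValueError("non-replicated cell carries a probeset_id")
        # every replicate group must contain at least 2 probes
        if rep.any():
            keys = [f"{p}\x1f{a}" for p, a in zip(pid.ravel(), alle.ravel())]
            _, counts = np.unique(np.asarray(keys), return_counts=True)
            if (counts < 2).any():
                raise ValueError(
                    "replicate group of size 1 labeled REPLICATED_SNP "
                    "(replicate groups must have >= 2 probes)"
                )


@dataclass
class IntensityGrid:
    """Rectangular array of per-cell intensities with a missing-value mask.

    ``values`` holds NaN at missing cells; on the RAW scale all non-missing
    values are >= 0.
    """

    values: np.ndarray
    scale: Scale
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        ok = ~self.missing_mask
        if self.scale is Scale.RAW and np.any(self.values[ok] < 0):
            raise ValueError("negative intensity on the RAW scale")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbesetIndex:
    """Materialized (probeset_id, allele) -> replicate-cell correspondence.

    ``keys`` is sorted by (probeset_id, allele); the flat ``rows``/``cols``
    arrays list every replicated cell grouped contiguously in key order and
    ``group_of[i]`` gives the key index of flat cell ``i`` — the layout used
    by all vectorized per-group reductions.
    """

    keys: list[tuple[str, str]]
    rows: np.ndarray
    cols: np.ndarray
    group_of: np.ndarray
    sizes: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.keys)

    @property
    def n_cells(self) -> int:
        return self.rows.size

    def group_cells(self, key: tuple[str, str]) -> list[tuple[int, int]]:
        """Ordered (y, x) replicate coordinates of one group."""
        gi = self.keys.index(key)
        sel = self.group_of == gi
        return list(zip(self.rows[sel].tolist(), self.cols[sel].tolist()))

    def values_at(self, grid_values: np.ndarray) -> np.ndarray:
        """Flat per-replicate values aligned with ``group_of``."""
        return grid_values[self.rows, self.cols]

    def group_reduce(self, flat: np.ndarray, how: str = "mean") -> np.ndarray:
        """Per-group mean or median of a flat replicate-aligned vector."""
        if how == "mean":
            return np.bincount(self.group_of, flat, self.n_groups) / self.sizes
        if how == "median":
            return (
                pd.Series(flat).groupby(self.group_of).median().to_numpy()
            )
        raise ValueError(f"unknown reduction {how!r}")


def build_probeset_index(layout: ChipLayout) -> ProbesetIndex:
    """Index every replicate group, ordered by (probeset_id, allele)."""
    ys, xs = np.nonzero(layout.replicated_mask())
    if ys.size == 0:
        return ProbesetIndex([], ys, xs, np.zeros(0, int), np.zeros(0, int))
    pids = layout.probeset_id[ys, xs].astype(str)
    alle = layout.allele[ys, xs].astype(str)
    order = np.lexsort((xs, ys, alle, pids))
    ys, xs, pids, alle = ys[order], xs[order], pids[order], alle[order]
    combo = np.char.add(np.char.add(pids, "\x1f"), alle)
    uniq, group_of = np.unique(combo, return_inverse=True)
    sizes = np.bincount(group_of, minlength=uniq.size)
    keys = [tuple(u.split("\x1f")) for u in uniq.tolist()]
    return ProbesetIndex(keys, ys, xs, group_of, sizes)


# ---------------------------------------------------------------------------
# probe-map TSV


def load_layout(path: str | Path, n_rows: int | None = None,
                n_cols: int | None = None) -> ChipLayout:
    """Read a probe-map TSV (columns ``x y class probeset_id allele``).

    Grid dimensions come from an optional first comment line
    ``# n_rows=R n_cols=C`` (written by :func:`write_layout`), from the
    ``n_rows``/``n_cols`` arguments, or default to max coordinate + 1.
    Cells absent from the file are EMPTY.
    """
    path = Path(path)
    header_dims: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                header_dims[k] = int(v)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    required = ["x", "y", "class", "probeset_id", "allele"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"probe-map is missing columns {missing_cols}")
    x = df["x"].astype(int).to_numpy()
    y = df["y"].astype(int).to_numpy()
    n_rows = n_rows or header_dims.get("n_rows") or (int(y.max()) + 1 if y.size else 0)
    n_cols = n_cols or header_dims.get("n_cols") or (int(x.max()) + 1 if x.size else 0)
    if np.any((x < 0) | (x >= n_cols) | (y < 0) | (y >= n_rows)):
        raise ValueError("probe-map coordinate outside the grid")
    dup = pd.DataFrame({"x": x, "y": y}).duplicated()
    if dup.any():
        i = int(np.nonzero(dup.to_numpy())[0][0])
        raise ValueError(f"duplicate cell coordinate (x={x[i]}, y={y[i]})")
    cell_class = np.full((n_rows, n_cols), CellClass.EMPTY, dtype=np.int8)
    probeset_id = np.full((n_rows, n_cols), None, dtype=object)
    allele = np.full((n_rows, n_cols), None, dtype=object)
    classes = df["class"].to_numpy()
    pids = df["probeset_id"].to_numpy()
    alls = df["allele"].to_numpy()
    for xi, yi, cl, pid, al in zip(x, y, classes, pids, alls):
        if cl not in _CLASS_FROM_TSV:
            raise ValueError(f"unknown cell class {cl!r}")
        c = _CLASS_FROM_TSV[cl]
        cell_class[yi, xi] = c
        if c is CellClass.REPLICATED_SNP:
            if not pid or al not in ("A", "B"):
                raise ValueError(
                    f"snp_rep cell (x={xi}, y={yi}) needs probeset_id and allele A/B"
                )
            probeset_id[yi, xi] = pid
            allele[yi, xi] = al
    return ChipLayout(n_rows, n_cols, cell_class, probeset_id, allele)


def write_layout(layout: ChipLayout, path: str | Path) -> None:
    """Write the probe-map TSV; EMPTY cells are omitted."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# n_rows={layout.n_rows} n_cols={layout.n_cols}\n")
        fh.write("x\ty\tclass\tprobeset_id\tallele\n")
        ys, xs = np.nonzero(layout.cell_class != CellClass.EMPTY)
        for yi, xi in zip(ys.tolist(), xs.tolist()):
            c = CellClass(layout.cell_class[yi, xi])
            pid = layout.probeset_id[yi, xi] or ""
            al = layout.allele[yi, xi] or ""
            fh.write(f"{xi}\t{yi}\t{_CLASS_TO_TSV[c]}\t{pid}\t{al}\n")


# ---------------------------------------------------------------------------
# intensity containers


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".cel":
        return "cel"
    if suffix == ".npz":
        return "npz"
    return "tsv"


def load_intensities(path: str | Path, layout: ChipLayout,
                     fmt: str | None = None) -> IntensityGrid:
    """Read a RAW-scale intensity grid; cells absent from the file are missing."""
    path = Path(path)
    fmt = fmt or _guess_format(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, na_values=["NA"],
                         keep_default_na=False, float_precision="round_trip")
        values = df.to_numpy(dtype=float)
    elif fmt == "npz":
        with np.load(path) as npz:
            values = np.asarray(npz["values"], dtype=float)
            mask = np.asarray(npz["missing"], dtype=bool)
        values = np.where(mask, np.nan, values)
    elif fmt == "cel":
        values = _read_cel_text(path)
    else:
        raise ValueError(f"unknown intensity format {fmt!r}")
    if values.shape != layout.shape:
        raise ValueError(
            f"intensity grid shape {values.shape} does not match layout {layout.shape}"
        )
    missing = np.isnan(values)
    if np.any(values[~missing] < 0):
        raise ValueError("negative intensity in input file")
    return IntensityGrid(values, Scale.RAW, missing)


def write_intensities(grid: IntensityGrid, path: str | Path,
                      fmt: str | None = None) -> None:
    """Write a RAW-scale grid; refuses GLOG-scale input.

    TSV and npz round-trip bit-for-value; the text CEL dialect prints MEAN
    with 6 significant digits and round-trips to that precision.
    """
    if grid.scale is not Scale.RAW:
        raise ValueError("only RAW-scale grids can be written (got GLOG)")
    path = Path(path)
    fmt = fmt or _guess_format(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            for row, miss in zip(grid.values, grid.missing_mask):
                fh.write("\t".join(
                    "NA" if m else format(v, ".17g")
                    for v, m in zip(row.tolist(), miss.tolist())
                ))
                fh.write("\n")
    elif fmt == "npz":
        np.savez(path, values=np.where(grid.missing_mask, np.nan, grid.values),
                 missing=grid.missing_mask)
    elif fmt == "cel":
        _write_cel_text(grid, path)
    else:
        raise ValueError(f"unknown intensity format {fmt!r}")


# ---------------------------------------------------------------------------
# text CEL version 3


def _read_cel_text(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    head = raw[:64].lstrip()
    if not head.startswith(b"[CEL]"):
        raise ValueError(
            "unsupported CEL dialect: expected text CEL v3 starting with [CEL] "
            "(binary GCOS/Calvin files are not supported)"
        )
    text = raw.decode("utf-8", errors="replace")
    section = None
    version = None
    n_rows = n_cols = None
    entries: list[tuple[int, int, float]] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].upper()
            in_data = False
            continue
        if section == "CEL" and line.lower().startswith("version="):
            version = line.split("=", 1)[1].strip()
        elif section == "HEADER":
            key, _, val = line.partition("=")
            key = key.strip().lower()
            if key == "cols":
                n_cols = int(val)
            elif key == "rows":
                n_rows = int(val)
        elif section == "INTENSITY":
            if "=" in line and not in_data:
                if line.lower().startswith("cellheader"):
                    in_data = True
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed [INTENSITY] line: {line!r}")
            entries.append((int(parts[0]), int(parts[1]), float(parts[2])))
    if version != "3":
        raise ValueError(f"unsupported CEL dialect: text CEL version {version!r}")
    if n_rows is None or n_cols is None:
        raise ValueError("text CEL v3 [HEADER] must declare Cols and Rows")
    values = np.full((n_rows, n_cols), np.nan)
    for x, y, mean in entries:
        if not (0 <= x < n_cols and 0 <= y < n_rows):
            raise ValueError(f"CEL entry (x={x}, y={y}) outside declared grid")
        values[y, x] = mean
    return values


def _write_cel_text(grid: IntensityGrid, path: Path) -> None:
    n_rows, n_cols = grid.shape
    ys, xs = np.nonzero(~grid.missing_mask)
    with open(path, "w") as fh:
        fh.write("[CEL]\nVersion=3\n\n")
        fh.write(f"[HEADER]\nCols={n_cols}\nRows={n_rows}\n\n")
        fh.write("[INTENSITY]\n")
        fh.write(f"NumberCells={ys.size}\n")
        fh.write("CellHeader=X\tY\tMEAN\tSTDV\tNPIXELS\n")
        for yi, xi in zip(ys.tolist(), xs.tolist()):
            fh.write(f"{xi}\t{yi}\t{format(grid.values[yi, xi], '.6g')}\t0.0\t9\n")
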