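import numpy as np
import pytest

import spnorm as sp


@pytest.fixture(scope="session")
def small_config() -> sp.SimulationConfig:
    """Desk-scale chip: 64x64 grid, 220 probesets, central stripes."""
    return sp.SimulationConfig(n_rows=64, n_cols=64, n_probesets=220,
                               stripe_width=2, seed=1)


@pytest.fixture(scope="session")
def small_chip(small_config):
    layout = sp.make_layout(small_config)
    index = sp.build_probeset_index(layout)
    grid, truth = sp.simulate_chip(layout, small_config, index=index)
    return layout, index, grid, truth


@pytest.fixture(scope="session")
def group_layout_factory():
    """Build a minimal layout + RAW grid holding given replicate groups.

    Lays each replicate group out on its own grid row (no adjacency or
    distance structure — only the group bookkeeping matters to the callers).
    """

    def build(values: np.ndarray, group_of: np.ndarray):
        values = np.asarray(values, dtype=float)
        n_groups = int(group_of.max()) + 1
        reps = np.bincount(group_of)
        n_cols = int(reps.max())
        cell_class = np.full((n_groups, n_cols), sp.CellClass.EMPTY, dtype=np.int8)
        pid = np.full((n_groups, n_cols), None, dtype=object)
        allele = np.full((n_groups, n_cols), None, dtype=object)
        grid = np.full((n_groups, n_cols), np.nan)
        col = np.zeros(n_groups, dtype=int)
        for v, g in zip(values, group_of):
            j = col[g]
            cell_class[g, j] = sp.CellClass.REPLICATED_SNP
            pid[g, j] = f"G{g:06d}"
            allele[g, j] = "A"
            grid[g, j] = v
            col[g] += 1
        layout = sp.ChipLayout(n_groups, n_cols, cell_class, pid, allele)
        igrid = sp.IntensityGrid(grid, sp.Scale.RAW, np.isnan(grid))
        return layout, sp.build_probeset_index(layout), igrid

    return build
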