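"""Render the fitted spatial bias field of a chip as a diagnostic map.

The bias field is the main exploratory byproduct of the normalization:
gradients show up as smooth color trends, blobs and scratches as sharp
local features, and the central stripes (non-replicated probes, no
estimate) as blank bands.  Writes bias_field.png next to this script.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import spnorm as sp

config = sp.SimulationConfig(n_rows=200, n_cols=200, n_probesets=2200, seed=12)
layout = sp.make_layout(config)
grid, truth = sp.simulate_chip(layout, config)
_, result = sp.normalize_chip(grid, layout)

field = result.field
shown = np.where(field.covered_mask, field.value, np.nan)
# percentile color scale, so subtle trends are visible next to deep scratches
ranks = np.full(shown.shape, np.nan)
vals = shown[field.covered_mask]
ranks[field.covered_mask] = vals.argsort().argsort() / (vals.size - 1)

fig, axes = plt.subplots(1, 2, figsize=(11, 5))
for ax, data, title in [(axes[0], truth.s_true, "injected bias S_true"),
                        (axes[1], ranks, "fitted field (percentile scale)")]:
    im = ax.imshow(data, origin="lower", cmap="RdBu_r", interpolation="nearest")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
out = Path(__file__).with_name("bias_field.png")
fig.savefig(out, dpi=130)

s = field.summary()
print(f"wrote {out}")
print(f"bias field median {s['median']:.4f}, "
      f"IQR ({s['iqr_low']:.4f}, {s['iqr_high']:.4f})")
# the IQR, a few hundredths of a glog unit, is the typical scale of the
# subtle biases; the scratch sits orders of magnitude outside it.
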