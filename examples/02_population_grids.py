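"""Population grid comparison between control and mutant groups.

Simulates two populations that differ only in the mass of the
posterior-preferring, TF-increasing ensemble (45% vs 12% of cells),
embeds all DS cells on two principal components of the amplitude+DSI
response matrix, segments an 8x8 grid, and classifies grids whose cell
fraction changed significantly in the mutant.
"""

import numpy as np

from dsstream.circstats import rayleigh_test
from dsstream.config import RunConfig
from dsstream.pipeline import analyze_population, simulate_groups

cfg = RunConfig(seed=1, n_cells_per_group=400)
curves, summaries, _ = simulate_groups(cfg)
rm, embedding, evr, assignment, cmp_ = analyze_population(summaries, curves, cfg)

print(f"DS cells embedded: {rm.matrix.shape[0]} "
      f"(PC1/PC2 explain {evr[0]:.0%}/{evr[1]:.0%} of variance)")
n_dec = int((cmp_.classes == "decreased").sum())
n_inc = int((cmp_.classes == "increased").sum())
print(f"grids decreased in mutant: {n_dec}, increased: {n_inc}")

dec = cmp_.classes == "decreased"
sel = np.array([dec[ix, iy] for ix, iy in assignment])
by_id = {s.cell_id: s for s in summaries}
ids = rm.cell_ids[sel]
ratios = [by_id[i].tf_ratio for i in ids]
thetas = [by_id[i].theta_per_tf[2] for i in ids
          if not np.isnan(by_id[i].theta_per_tf[2])]
_, p, _ = rayleigh_test(thetas)
print(f"decreased-grid cells: median amplitude ratio 1.2/0.3 Hz = "
      f"{np.nanmedian(ratios):.2f} (>1: TF-increasing)")
print(f"their preferred directions at 1.2 Hz are non-uniform "
      f"(Rayleigh p = {p:.2e}), biased toward posterior (0 deg)")
print(f"mutation index in decreased grids: "
      f"{np.round(cmp_.mi[dec], 2)} (positive = lost in mutant)")
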