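"""Screen gene panels over a finished run.

Builds a simulated run, renames a few genes to panel members with chosen
behavior, then asks two questions: which panel genes are highly expressed,
and which respond to the treatment?
"""

import numpy as np

from permdeg import (
    CountMatrix,
    SimConfig,
    check_unresponsive,
    load_builtin_panel,
    call_degs,
    simulate_counts,
    tmm_factors,
)

cm, _ = simulate_counts(SimConfig(n_genes=2000, de_fraction=0.0, seed=5))

# plant the SLC panel: two abundant responsive transporters, one abundant
# silent one, and one at trace expression; plus a silent melanogenesis trio
gene_ids = list(cm.gene_ids)
counts = cm.counts.copy()
planted = {
    "SLC7A1": (400, 8.0), "SLC22A18": (300, 0.25), "SLC3A2": (500, 1.0),
    "SLC18B1": (2, 1.0), "TYR": (80, 1.0), "TYRP1": (60, 1.0), "DCT": (40, 1.0),
}
rng = np.random.default_rng(0)
for i, (name, (level, effect)) in enumerate(planted.items()):
    gene_ids[i] = name
    counts[i, :3] = rng.poisson(level, 3)
    counts[i, 3:] = rng.poisson(level * effect, 3)
cm = CountMatrix(gene_ids, cm.sample_ids, counts, cm.groups, cm.control_label)

norm = tmm_factors(cm)
deg = call_degs(norm, cm.groups, cm.control_label)

slc = load_builtin_panel("slc_named")
from permdeg import screen_panel

report = screen_panel(slc, deg, norm, expr_cutoff=10.0)
print(report.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

mel = load_builtin_panel("melanogenesis")
print("\nunresponsive melanogenesis genes:", check_unresponsive(mel, deg))

# SLC7A1/SLC22A18 are highly expressed AND responsive (up/down), SLC3A2 is
# highly expressed but silent, SLC18B1 falls below the 10-CPM expression
# cutoff; the melanogenesis trio shows no transcriptional response.
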