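"""Gene-panel screens over a finished differential-expression run.

Two questions are asked of a panel: which members are *highly expressed*
(mean CPM across all samples above a cutoff, or alternatively the top-k
within the panel), and which are *responsive* to the treatment (carry a
non-none DEG call).  Panel genes absent from the matrix are reported as
absent, never silently dropped.

Shipped panels (under ``permdeg/data/``):

* ``melanogenesis.tsv`` — the tyrosinase-family genes TYR, TYRP1 (TRP-1)
  and DCT (TRP-2), the canonical melanin-synthesis panel;
* ``slc_named.tsv`` — SLC3A2, SLC7A1, SLC18B1, SLC22A18, solute-carrier
  transporters implicated in polyamine uptake;
* ``proteolysis_example.tsv`` — an illustrative ubiquitin–proteasome panel
  for demonstration purposes only.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError
from .io import GenePanel, read_panel
from .normalization import NormalizationResult

__all__ = [
    "screen_panel",
    "check_unresponsive",
    "load_builtin_panel",
    "BUILTIN_PANELS",
]

BUILTIN_PANELS = ("melanogenesis", "slc_named", "proteolysis_example")

DEFAULT_EXPR_CUTOFF = 10.0


def load_builtin_panel(name: str) -> GenePanel:
    """Load one of the panels shipped with the package."""
    if name not in BUILTIN_PANELS:
        raise DesignError(f"unknown builtin panel {name!r}; choose from {BUILTIN_PANELS}")
    ref = resources.files("permdeg").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as path:
        return read_panel(Path(path), name=name)


def screen_panel(
    panel: GenePanel,
    deg: pd.DataFrame,
    norm: NormalizationResult,
    expr_cutoff: float = DEFAULT_EXPR_CUTOFF,
    alpha: float = 0.05,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Screen a panel for highly expressed and treatment-responsive members.

    ``highly_expressed`` is mean CPM across *all* samples >= ``expr_cutoff``;
    with ``top_k`` set, the rank rule is used instead: the k panel members
    with the highest mean CPM are flagged.  ``responsive`` copies the
    direction of the gene's DEG call.  Absent genes get ``present=False``
    and all flags false/none.

    Returns one row per panel gene, in panel order.
    """
    if not panel.gene_ids:
        raise DesignError("empty panel")
    deg_idx = deg.set_index("gene_id")
    cpm_mean = pd.Series(norm.cpm.mean(axis=1), index=norm.gene_ids)

    rows = []
    for gene in panel.gene_ids:
        present = gene in deg_idx.index
        if present:
            rec = deg_idx.loc[gene]
            rows.append(
                {
                    "gene_id": gene,
                    "present": True,
                    "mean_cpm_control": float(rec["mean_cpm_control"]),
                    "mean_cpm_treated": float(rec["mean_cpm_treated"]),
                    "mean_cpm_all": float(cpm_mean.get(gene, np.nan)),
                    "responsive": str(rec["call"]),
                    "p_adj": float(rec["p_adj"]),
                }
            )
        else:
            rows.append(
                {
                    "gene_id": gene,
                    "present": False,
                    "mean_cpm_control": np.nan,
                    "mean_cpm_treated": np.nan,
                    "mean_cpm_all": np.nan,
                    "responsive": "none",
                    "p_adj": np.nan,
                }
            )
    report = pd.DataFrame(rows)

    if top_k is not None:
        ranked = report.loc[report["present"]].sort_values(
            "mean_cpm_all", ascending=False, kind="stable"
        )
        top = set(ranked["gene_id"].head(top_k))
        report["highly_expressed"] = report["gene_id"].isin(top)
    else:
        report["highly_expressed"] = report["present"] & (
            report["mean_cpm_all"] >= expr_cutoff
        )
    report.attrs["panel"] = panel.name
    report.attrs["expr_cutoff"] = expr_cutoff
    report.attrs["alpha"] = alpha
    cols = [
        "gene_id",
        "present",
        "mean_cpm_control",
        "mean_cpm_treated",
        "mean_cpm_all",
        "highly_expressed",
        "responsive",
        "p_adj",
    ]
    return report[cols]


def check_unresponsive(panel: GenePanel, deg: pd.DataFrame) -> list[str]:
    """Panel genes present in the DEG table whose call is none, in order.

    The use case is confirming that a pathway the treatment is *not*
    expected to touch transcriptionally (e.g. the melanogenesis panel)
    indeed shows no differential calls.
    """
    deg_idx = deg.set_index("gene_id")["call"]
    return [
        g for g in panel.gene_ids if g in deg_idx.index and deg_idx[g] == "none"
    ]
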