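"""End-to-end orchestration: counts -> TMM -> permutation DE -> summary.

The pipeline is deterministic given a configuration and seed; the run
summary echoes every effective setting so a run can be reproduced from its
log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .errors import ConfigError
from .io import CountMatrix, read_counts, read_groups, write_deg_table
from .normalization import NormalizationResult, tmm_factors
from .permtest import (
    DEFAULT_ASSIGNMENT_CAP,
    Thresholds,
    call_degs,
    enumerate_assignments,
    format_fold_change,
)

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline", "run_from_matrix"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run (YAML-loadable)."""

    control_label: str = "CTL"
    alpha: float = 0.05
    fc_lower_pct: float = 0.5
    fc_upper_pct: float = 99.5
    pseudocount: float = 0.5
    min_cpm_filter: float = 1.0
    min_samples_filter: int | None = None
    filter_enabled: bool = True
    welch: bool = False
    bh: bool = False
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    tmm_reference: str = "auto"
    cap: int | None = DEFAULT_ASSIGNMENT_CAP
    seed: int = 0
    allow_noninteger: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            alpha=self.alpha,
            fc_lower_pct=self.fc_lower_pct,
            fc_upper_pct=self.fc_upper_pct,
            pseudocount=self.pseudocount,
            min_cpm_filter=self.min_cpm_filter,
            min_samples_filter=self.min_samples_filter,
            filter_enabled=self.filter_enabled,
            welch=self.welch,
            bh=self.bh,
        )


@dataclasses.dataclass
class RunSummary:
    """Headline numbers of a run, in the shape results are reported."""

    n_genes_input: int
    n_genes_filtered: int
    n_assignments: int
    log2fc_cutoff: float
    n_up: int
    n_down: int
    alpha: float
    seed: int
    config_echo: dict[str, Any]

    @property
    def fold_change_cutoff(self) -> str:
        """The |log2FC| cutoff expressed as a linear fold change, 2 d.p."""
        return format_fold_change(self.log2fc_cutoff)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["fold_change_cutoff"] = self.fold_change_cutoff
        return d

    def to_text(self) -> str:
        lines = [
            f"genes in input          : {self.n_genes_input}",
            f"genes failing filter    : {self.n_genes_filtered}",
            f"label assignments       : {self.n_assignments}",
            f"|log2FC| cutoff (null)  : {self.log2fc_cutoff:.4g} "
            f"({self.fold_change_cutoff}-fold)",
            f"alpha                   : {self.alpha}",
            f"upregulated genes       : {self.n_up}",
            f"downregulated genes     : {self.n_down}",
            f"seed                    : {self.seed}",
            "config                  : "
            + json.dumps(self.config_echo, sort_keys=True, default=str),
        ]
        return "\n".join(lines)


def run_from_matrix(
    cm: CountMatrix, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, RunSummary, NormalizationResult]:
    """Run normalization and DEG calling on an in-memory count matrix."""
    config = config or PipelineConfig()
    if cm.groups is None:
        raise ConfigError("count matrix has no group design attached")

    t0 = time.perf_counter()
    norm = tmm_factors(
        cm,
        trim_m=config.tmm_trim_m,
        trim_a=config.tmm_trim_a,
        reference=config.tmm_reference,
    )
    logger.info(
        "normalization: reference=%s, %.2fs",
        norm.reference_sample,
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    scheme = enumerate_assignments(
        cm.groups, cm.sample_ids, cm.control_label, cap=config.cap, seed=config.seed
    )
    table = call_degs(
        norm,
        cm.groups,
        cm.control_label,
        thresholds=config.thresholds(),
        scheme=scheme,
    )
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    logger.info(
        "deg calling: %d assignments, cutoff=%.4g, %d up / %d down, %.2fs",
        scheme.n_assignments,
        table.attrs["log2fc_cutoff"],
        n_up,
        n_down,
        time.perf_counter() - t0,
    )

    summary = RunSummary(
        n_genes_input=cm.n_genes,
        n_genes_filtered=table.attrs["n_filtered"],
        n_assignments=scheme.n_assignments,
        log2fc_cutoff=table.attrs["log2fc_cutoff"],
        n_up=n_up,
        n_down=n_down,
        alpha=config.alpha,
        seed=config.seed,
        config_echo=dataclasses.asdict(config),
    )
    return table, summary, norm


def run_pipeline(
    counts_path: str | Path,
    groups_path: str | Path,
    config: PipelineConfig | None = None,
    out_path: str | Path | None = None,
    counts_format: str = "tsv",
) -> tuple[pd.DataFrame, RunSummary]:
    """Read inputs, run the pipeline, optionally write results + summary.

    When ``out_path`` is given the DEG table is written there and the run
    summary alongside it as ``<out>.summary.json``.
    """
    config = config or PipelineConfig()
    cm = read_counts(
        counts_path, format=counts_format, allow_noninteger=config.allow_noninteger
    )
    groups = read_groups(groups_path)
    cm.set_groups(groups, config.control_label)
    table, summary, _norm = run_from_matrix(cm, config)
    if out_path is not None:
        out_path = Path(out_path)
        write_deg_table(table, out_path)
        out_path.with_suffix(out_path.suffix + ".summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
        )
    return table, summary
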