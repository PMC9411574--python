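"""Seeded negative-binomial count simulation with spiked-in effects.

Emulates the statistical structure a small bulk RNA-seq comparison assumes:
gene-wise log-normal baseline means, NB sampling noise with configurable
overdispersion (variance = mu + phi * mu^2), unequal library depths, a
small replicated two-group design, and a configurable fraction of genes
carrying true log2 fold-change effects.  Ground truth is returned so
calibration (type-I error) and recovery (sensitivity/FDR) can be scored.

Defaults mirror the target study design: 3 control vs 3 treated replicates,
~2000 genes, library sizes 0.7-1.3 million.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import ConfigError, MismatchError
from .io import CountMatrix

__all__ = ["SimConfig", "simulate_counts", "evaluate_run"]

CONTROL_LABEL = "CTL"
TREATED_LABEL = "SPD"


@dataclasses.dataclass
class SimConfig:
    """Parameters of the count simulator.

    Parameters
    ----------
    n_genes
        Number of genes.
    n_per_group
        (control, treated) replicate counts.
    lib_size_range
        Library-size bounds as multiples of one million reads.
    mean_log_mu, sd_log_mu
        Natural-log mean and sd of the log-normal distribution of baseline
        per-million expression levels (default centers genes near 50 CPM).
    dispersion
        NB overdispersion phi in variance = mu + phi*mu^2; a float for a
        common value, or "trended" for phi_g = 0.05 + 5/mu_g (small genes
        noisier), the shape empirical mean-dispersion trends take.
    de_fraction
        Fraction of genes given a true effect.
    de_log2fc
        Magnitude of the true log2 fold-change, a scalar or (low, high)
        range sampled uniformly per DE gene.
    de_direction_balance
        Fraction of DE genes that are upregulated.
    composition_bias
        If set, multiply a random 5% of genes in the last sample by this
        factor — an asymmetric composition shift that TMM must absorb.
    seed
        Seed for all randomness; identical configs reproduce bit-identical
        matrices.
    """

    n_genes: int = 2000
    n_per_group: tuple[int, int] = (3, 3)
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    mean_log_mu: float = math.log(50.0)
    sd_log_mu: float = 1.5
    dispersion: float | str = 0.1
    de_fraction: float = 0.05
    de_log2fc: float | tuple[float, float] = 2.0
    de_direction_balance: float = 0.5
    composition_bias: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if min(self.n_per_group) < 2:
            raise ConfigError("need >= 2 replicates per group")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigError("lib_size_range must be positive and ordered")
        if isinstance(self.dispersion, str):
            if self.dispersion != "trended":
                raise ConfigError("dispersion must be a positive float or 'trended'")
        elif self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ConfigError("de_fraction must be in [0, 1)")
        if not 0.0 <= self.de_direction_balance <= 1.0:
            raise ConfigError("de_direction_balance must be in [0, 1]")

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_genes)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its ground truth from the configured model.

    Gene baselines mu_g ~ LogNormal(mean_log_mu, sd_log_mu) are per-million
    rates; sample s draws NB counts with mean mu_g * L_s / 1e6 (times the
    effect 2^(+-log2fc) in the treated group for DE genes), realized as a
    gamma-Poisson mixture.  DE genes are a seeded random subset so truth is
    not confounded with gene order.

    Returns the count matrix (groups attached, control label "CTL") and a
    truth frame with columns ``gene_id, base_mean, true_log2fc, is_de``.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n0, n1 = config.n_per_group
    width = max(6, len(str(g)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(g)]
    sample_ids = [f"{CONTROL_LABEL}{i + 1}" for i in range(n0)] + [
        f"{TREATED_LABEL}{i + 1}" for i in range(n1)
    ]
    groups = {s: (CONTROL_LABEL if i < n0 else TREATED_LABEL) for i, s in enumerate(sample_ids)}

    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=g)

    true_lfc = np.zeros(g)
    n_de = config.n_de
    if n_de:
        de_idx = rng.permutation(g)[:n_de]
        n_up = round(config.de_direction_balance * n_de)
        signs = np.where(np.arange(n_de) < n_up, 1.0, -1.0)
        if isinstance(config.de_log2fc, tuple):
            lo, hi = config.de_log2fc
            magnitude = rng.uniform(lo, hi, size=n_de)
        else:
            magnitude = np.full(n_de, float(config.de_log2fc))
        true_lfc[de_idx] = signs * magnitude

    lib_lo, lib_hi = config.lib_size_range
    lib_sizes = rng.uniform(lib_lo * 1e6, lib_hi * 1e6, size=n0 + n1)

    # per-gene per-sample means: baseline scaled by depth, effect in treated
    mean_grid = mu[:, None] * (lib_sizes[None, :] / 1e6)
    mean_grid[:, n0:] *= 2.0 ** true_lfc[:, None]

    if isinstance(config.dispersion, str):
        phi = 0.05 + 5.0 / mu
    else:
        phi = np.full(g, float(config.dispersion))
    shape = 1.0 / phi
    lam = rng.gamma(shape[:, None], mean_grid * phi[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    if config.composition_bias is not None:
        n_biased = max(1, g // 20)
        biased = rng.permutation(g)[:n_biased]
        counts[biased, -1] = np.round(counts[biased, -1] * config.composition_bias).astype(
            np.int64
        )

    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=counts,
        groups=groups,
        control_label=CONTROL_LABEL,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": mu,
            "true_log2fc": true_lfc,
            "is_de": true_lfc != 0.0,
        }
    )
    return cm, truth


def evaluate_run(deg: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Score a DEG table against simulator ground truth.

    Metrics: ``type_i_error`` (calls among truly null genes / null genes),
    ``sensitivity`` (correct-direction calls among DE genes / DE genes),
    ``fdr`` (false calls — null-gene calls plus wrong-direction calls —
    over all calls; 0 when nothing is called), plus the run's derived
    ``log2fc_cutoff`` when available.
    """
    if set(deg["gene_id"]) != set(truth["gene_id"]):
        raise MismatchError("DEG table and truth cover different gene sets")
    merged = deg.merge(truth, on="gene_id", validate="one_to_one")
    called = merged["call"] != "none"
    is_de = merged["is_de"].to_numpy()
    n_null = int((~is_de).sum())
    n_de = int(is_de.sum())

    sign = np.sign(merged["true_log2fc"].to_numpy())
    call_sign = merged["call"].map({"up": 1.0, "down": -1.0, "none": 0.0}).to_numpy()
    correct = called & is_de & (call_sign == sign)
    false_calls = int((called & ~correct).sum())
    n_calls = int(called.sum())

    metrics = {
        "type_i_error": float((called & ~is_de).sum() / n_null) if n_null else 0.0,
        "sensitivity": float(correct.sum() / n_de) if n_de else 0.0,
        "fdr": float(false_calls / n_calls) if n_calls else 0.0,
        "n_calls": float(n_calls),
    }
    if "log2fc_cutoff" in deg.attrs:
        metrics["log2fc_cutoff"] = float(deg.attrs["log2fc_cutoff"])
    return metrics
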