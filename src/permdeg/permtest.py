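"""Permutation-null differential expression for two-group designs.

The procedure: per-gene two-sample t-statistics on TMM-normalized CPM, an
empirical null built by recomputing the statistic under every possible
relabelling of the samples (exhaustive for small designs), gene-pooled
empirical p-values, and a fold-change cutoff read off the tails of the null
log2 fold-change distribution.  Genes are called differentially expressed
when they clear both the p-value cutoff and the null-derived |log2FC|
cutoff.

With three replicates per group there are C(6,3) = 20 label assignments, so
a single gene's permutation p-value can never fall below 1/20; pooling the
19 non-identity assignments across all G genes gives the null a resolution
of 1/(1 + 19 G), which is what makes per-gene values below 0.05 attainable.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .io import CountMatrix
from .normalization import NormalizationResult, cpm_means_by_group

__all__ = [
    "Thresholds",
    "PermutationScheme",
    "NullDistribution",
    "t_statistic",
    "t_statistics",
    "log2fc",
    "enumerate_assignments",
    "build_null",
    "empirical_p",
    "derive_fc_cutoff",
    "expression_filter",
    "call_degs",
    "fold_change",
]

logger = logging.getLogger(__name__)

DEFAULT_ASSIGNMENT_CAP = 10_000


@dataclasses.dataclass
class Thresholds:
    """Decision thresholds for DEG calling.

    ``log2fc_cutoff`` is *derived* from the permutation null (mean of the
    absolute ``fc_lower_pct`` and ``fc_upper_pct`` percentiles of null
    log2FC), not set by the user.  ``min_samples_filter=None`` means "the
    smaller group size".
    """

    alpha: float = 0.05
    fc_lower_pct: float = 0.5
    fc_upper_pct: float = 99.5
    pseudocount: float = 0.5
    min_cpm_filter: float = 1.0
    min_samples_filter: int | None = None
    filter_enabled: bool = True
    welch: bool = False
    bh: bool = False
    log2fc_cutoff: float | None = None  # derived

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.fc_lower_pct >= self.fc_upper_pct:
            raise ConfigError("fc_lower_pct must be < fc_upper_pct")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")


@dataclasses.dataclass
class PermutationScheme:
    """All group-label assignments used for the null, observed one first.

    Each assignment is a boolean vector over the sample order, True marking
    the pseudo-treated samples; every assignment preserves the original
    group sizes and all are distinct.
    """

    assignments: np.ndarray  # (n_assignments, n_samples) boolean
    exhaustive: bool

    @property
    def n_assignments(self) -> int:
        return self.assignments.shape[0]

    @property
    def observed(self) -> np.ndarray:
        return self.assignments[0]


@dataclasses.dataclass
class NullDistribution:
    """Pooled permutation-null statistics across genes and assignments."""

    null_t: np.ndarray
    null_log2fc: np.ndarray
    n_assignments_used: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.null_log2fc)):
            raise ValueError("null log2FC must be finite (pseudocount guarantees this)")


# ---------------------------------------------------------------------------
# statistics


def t_statistics(
    ctl: np.ndarray, trt: np.ndarray, welch: bool = False
) -> np.ndarray:
    """Row-wise two-sample t-statistics, treated minus control.

    The default is the classical pooled-variance (equal-variance) Student
    statistic.  Zero-variance rows get t = 0 when the means agree and a
    signed infinity sentinel when they differ, so ordering by |t| survives
    degenerate genes without NaNs.
    """
    ctl = np.atleast_2d(np.asarray(ctl, dtype=float))
    trt = np.atleast_2d(np.asarray(trt, dtype=float))
    n0, n1 = ctl.shape[1], trt.shape[1]
    if n0 < 2 or n1 < 2:
        raise DesignError(f"need >= 2 samples per group, got {n0} and {n1}")
    diff = trt.mean(axis=1) - ctl.mean(axis=1)
    v0 = ctl.var(axis=1, ddof=1)
    v1 = trt.var(axis=1, ddof=1)
    if welch:
        se = np.sqrt(v0 / n0 + v1 / n1)
    else:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    return t


def t_statistic(x: Sequence[float], y: Sequence[float], welch: bool = False) -> float:
    """Scalar two-sample t of treated ``y`` versus control ``x``."""
    return float(t_statistics(np.asarray(x)[None, :], np.asarray(y)[None, :], welch)[0])


def log2fc(
    mean_ctl: float | np.ndarray,
    mean_trt: float | np.ndarray,
    pseudocount: float = 0.5,
) -> float | np.ndarray:
    """Pseudocounted log2 fold-change, treated over control; always finite."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    out = np.log2(
        (np.asarray(mean_trt, dtype=float) + pseudocount)
        / (np.asarray(mean_ctl, dtype=float) + pseudocount)
    )
    return float(out) if out.ndim == 0 else out


def fold_change(log2fc_value: float) -> float:
    """Linear fold change corresponding to a log2 fold-change."""
    return float(2.0 ** log2fc_value)


def format_fold_change(log2fc_value: float) -> str:
    """Human-readable fold change at two decimals, e.g. 0.428 -> '1.35'."""
    return f"{fold_change(log2fc_value):.2f}"


# ---------------------------------------------------------------------------
# permutation scheme


def enumerate_assignments(
    groups: dict[str, str],
    sample_ids: Sequence[str],
    control_label: str,
    cap: int | None = DEFAULT_ASSIGNMENT_CAP,
    seed: int = 0,
) -> PermutationScheme:
    """Enumerate group-label assignments preserving the group sizes.

    If the total number of distinct assignments C(n, n_treated) fits under
    ``cap`` the enumeration is exhaustive, in lexicographic order of the
    treated index set, with the observed assignment moved to the front.
    Otherwise the observed assignment is kept and ``cap - 1`` further
    distinct assignments are drawn without replacement using ``seed``.
    """
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise DesignError(f"samples without group labels: {missing}")
    observed = np.array([groups[s] != control_label for s in sample_ids])
    n = len(sample_ids)
    n1 = int(observed.sum())
    if n1 == 0 or n1 == n:
        raise DesignError("both groups must be non-empty")
    total = math.comb(n, n1)

    def as_mask(combo: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        m[list(combo)] = True
        return m

    observed_combo = tuple(np.flatnonzero(observed))
    if cap is None or total <= cap:
        combos = [observed_combo] + [
            c for c in itertools.combinations(range(n), n1) if c != observed_combo
        ]
        return PermutationScheme(
            assignments=np.array([as_mask(c) for c in combos]), exhaustive=True
        )

    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = {observed_combo}
    combos = [observed_combo]
    # rejection sampling; collision probability is negligible when total >> cap
    while len(combos) < cap:
        c = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if c not in chosen:
            chosen.add(c)
            combos.append(c)
    return PermutationScheme(
        assignments=np.array([as_mask(c) for c in combos]), exhaustive=False
    )


# ---------------------------------------------------------------------------
# the empirical null


def build_null(
    norm: NormalizationResult,
    scheme: PermutationScheme,
    thresholds: Thresholds,
    keep: np.ndarray | None = None,
) -> NullDistribution:
    """Pool t and log2FC over all non-identity assignments and kept genes.

    For every assignment after the observed one, each gene's t-statistic and
    pseudocounted log2FC are recomputed on the CPM matrix with the permuted
    labels; the results are flattened into one pooled null per statistic.
    Infinite t sentinels are stored as such (they occur when a permuted
    split has zero within-group variance).
    """
    if scheme.n_assignments < 2:
        raise DesignError("scheme has no non-identity assignments")
    cpm = norm.cpm if keep is None else norm.cpm[keep]
    n_perm = scheme.n_assignments - 1
    n_genes = cpm.shape[0]
    null_t = np.empty((n_perm, n_genes))
    null_fc = np.empty((n_perm, n_genes))
    for i, mask in enumerate(scheme.assignments[1:]):
        ctl = cpm[:, ~mask]
        trt = cpm[:, mask]
        null_t[i] = t_statistics(ctl, trt, welch=thresholds.welch)
        null_fc[i] = log2fc(
            ctl.mean(axis=1), trt.mean(axis=1), thresholds.pseudocount
        )
    return NullDistribution(
        null_t=null_t.ravel(),
        null_log2fc=null_fc.ravel(),
        n_assignments_used=scheme.n_assignments,
    )


def empirical_p(observed_t: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Two-tailed gene-pooled empirical p-values with add-one smoothing.

    ``p_g = (1 + #{v in null : |v| >= |t_g|}) / (1 + N)`` where N is the
    pooled null size.  Infinite null values count as exceeding everything;
    an infinite observed t is only exceeded by (tied with) infinite null
    values.  Values are therefore always in (0, 1].
    """
    observed_t = np.asarray(observed_t, dtype=float)
    abs_null = np.abs(null.null_t)
    n_total = abs_null.size
    if n_total == 0:
        raise DesignError("empty null distribution")
    finite = np.sort(abs_null[np.isfinite(abs_null)])
    n_inf = n_total - finite.size
    abs_obs = np.abs(observed_t)
    exceed = np.full(observed_t.shape, n_inf, dtype=float)
    finite_obs = np.isfinite(abs_obs)
    # count of finite null values >= |t|
    exceed[finite_obs] += finite.size - np.searchsorted(
        finite, abs_obs[finite_obs], side="left"
    )
    return (1.0 + exceed) / (1.0 + n_total)


def derive_fc_cutoff(null: NullDistribution, thresholds: Thresholds) -> float:
    """Fold-change cutoff from the tails of the null log2FC distribution.

    The cutoff is the mean of the absolute lower and upper percentiles
    (defaults 0.5 and 99.5) of the pooled null log2FC values, percentiles
    computed with linear interpolation between order statistics.  The
    result is stored back into ``thresholds.log2fc_cutoff``.
    """
    if null.null_log2fc.size == 0:
        raise DesignError("empty null log2FC distribution")
    lo = np.percentile(null.null_log2fc, thresholds.fc_lower_pct)
    hi = np.percentile(null.null_log2fc, thresholds.fc_upper_pct)
    cutoff = float((abs(lo) + abs(hi)) / 2.0)
    thresholds.log2fc_cutoff = cutoff
    return cutoff


# ---------------------------------------------------------------------------
# filtering and calling


def expression_filter(
    norm: NormalizationResult,
    groups: dict[str, str],
    control_label: str,
    thresholds: Thresholds,
) -> np.ndarray:
    """Boolean keep-mask: CPM >= min_cpm_filter in >= min_samples samples.

    The sample threshold defaults to the smaller group size so that a gene
    expressed in only one full group is retained.
    """
    if not thresholds.filter_enabled:
        return np.ones(len(norm.gene_ids), dtype=bool)
    labels = [groups[s] for s in norm.sample_ids]
    sizes = [labels.count(lab) for lab in sorted(set(labels))]
    min_samples = (
        thresholds.min_samples_filter
        if thresholds.min_samples_filter is not None
        else min(sizes)
    )
    return (norm.cpm >= thresholds.min_cpm_filter).sum(axis=1) >= min_samples


def call_degs(
    norm: NormalizationResult,
    groups: dict[str, str],
    control_label: str,
    thresholds: Thresholds | None = None,
    scheme: PermutationScheme | None = None,
    cap: int | None = DEFAULT_ASSIGNMENT_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full calling procedure and return the per-gene DEG table.

    Steps: low-expression filter, observed t and log2FC per gene, pooled
    permutation null over the *kept* genes, fold-change cutoff from the
    null, empirical p-values, and up/down/none calls.  Fully deterministic
    given the inputs, thresholds and seed.

    Returns a DataFrame with columns ``gene_id, mean_cpm_control,
    mean_cpm_treated, log2fc, t_stat, p_adj, call, filtered`` and the run
    metadata in ``df.attrs`` (``log2fc_cutoff``, ``n_assignments``,
    ``alpha``, ``n_filtered``).
    """
    thresholds = thresholds if thresholds is not None else Thresholds()
    if scheme is None:
        scheme = enumerate_assignments(
            groups, norm.sample_ids, control_label, cap=cap, seed=seed
        )
    keep = expression_filter(norm, groups, control_label, thresholds)

    means = cpm_means_by_group(norm, groups, control_label)
    mask = scheme.observed
    obs_t = t_statistics(norm.cpm[:, ~mask], norm.cpm[:, mask], welch=thresholds.welch)
    obs_fc = log2fc(
        means["mean_cpm_control"].to_numpy(),
        means["mean_cpm_treated"].to_numpy(),
        thresholds.pseudocount,
    )

    null = build_null(norm, scheme, thresholds, keep=keep)
    cutoff = derive_fc_cutoff(null, thresholds)
    p_adj = empirical_p(obs_t, null)
    if thresholds.bh:
        p_adj = _benjamini_hochberg(p_adj)

    n_inf = int(np.sum(~np.isfinite(obs_t)))
    if n_inf:
        logger.warning("%d genes have infinite t sentinels", n_inf)

    significant = keep & (p_adj <= thresholds.alpha)
    call = np.where(
        significant & (obs_fc > cutoff),
        "up",
        np.where(significant & (obs_fc < -cutoff), "down", "none"),
    )
    table = pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "mean_cpm_control": means["mean_cpm_control"].to_numpy(),
            "mean_cpm_treated": means["mean_cpm_treated"].to_numpy(),
            "log2fc": obs_fc,
            "t_stat": obs_t,
            "p_adj": p_adj,
            "call": call,
            "filtered": ~keep,
        }
    )
    table.attrs["log2fc_cutoff"] = cutoff
    table.attrs["n_assignments"] = scheme.n_assignments
    table.attrs["alpha"] = thresholds.alpha
    table.attrs["n_filtered"] = int((~keep).sum())
    table.attrs["n_inf_t"] = n_inf
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Optional BH pass over the pooled empirical p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
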