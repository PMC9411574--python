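"""Trimmed-mean-of-M-values (TMM) library normalization and CPM.

TMM corrects between-sample composition bias by comparing each sample to a
reference sample on the log-ratio (M) / log-abundance (A) plane, discarding
the most extreme genes on both axes, and averaging the surviving M-values
with precision weights.  The resulting scaling factors multiply the raw
library sizes to give *effective* library sizes; counts-per-million (CPM)
are computed against those.

The recipe is fixed so factors are reproducible across implementations:

* reference sample: the one whose 75th-percentile count fraction is closest
  to the across-sample mean of those fractions;
* per sample vs reference, over genes with nonzero counts in both:
  ``M = log2((y_s/N_s)/(y_r/N_r))``, ``A = 0.5*log2((y_s/N_s)*(y_r/N_r))``;
* trim the top and bottom 30% of genes by M and 5% by A (ranks, ties
  averaged), keep the intersection;
* factor = ``2**weighted_mean(M)`` with inverse asymptotic-variance weights
  ``1/(1/y_s - 1/N_s + 1/y_r - 1/N_r)``;
* rescale all factors so their geometric mean is exactly 1.

If fewer than 10 genes survive trimming for some sample, its factor falls
back to 1 with a warning.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DesignError, NormalizationError
from .io import CountMatrix

__all__ = ["NormalizationResult", "tmm_factors", "cpm_means_by_group"]

logger = logging.getLogger(__name__)

MIN_TRIMMED_GENES = 10


@dataclasses.dataclass
class NormalizationResult:
    """TMM factors, library sizes and the derived CPM matrix.

    ``cpm[g, s] = counts[g, s] / (lib_sizes[s] * factors[s]) * 1e6`` and the
    geometric mean of the factors is 1.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    factors: dict[str, float]
    lib_sizes: dict[str, int]
    cpm: np.ndarray
    reference_sample: str

    def factor_array(self) -> np.ndarray:
        return np.array([self.factors[s] for s in self.sample_ids])

    def lib_size_array(self) -> np.ndarray:
        return np.array([self.lib_sizes[s] for s in self.sample_ids])

    def cpm_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cpm, index=self.gene_ids, columns=self.sample_ids)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    sample_id: str,
) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    both = (obs > 0) & (ref > 0)
    y_s = obs[both].astype(float)
    y_r = ref[both].astype(float)
    p_s = y_s / n_obs
    p_r = y_r / n_ref
    m = np.log2(p_s / p_r)
    a = 0.5 * np.log2(p_s * p_r)
    # inverse of the delta-method binomial variance of M
    var = 1.0 / y_s - 1.0 / n_obs + 1.0 / y_r - 1.0 / n_ref
    n = m.size
    if n == 0:
        logger.warning("TMM: no shared nonzero genes for sample %s; factor=1", sample_id)
        return 0.0
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < MIN_TRIMMED_GENES:
        logger.warning(
            "TMM: only %d genes survive trimming for sample %s; falling back "
            "to factor=1",
            keep.sum(),
            sample_id,
        )
        return 0.0
    w = 1.0 / var[keep]
    return float(np.sum(m[keep] * w) / np.sum(w))


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str = "auto",
) -> NormalizationResult:
    """Compute TMM scaling factors and the CPM matrix for a count matrix.

    Parameters
    ----------
    counts
        Validated count matrix with at least two samples.
    trim_m, trim_a
        Two-sided trim fractions on the M (log-ratio) and A (log-abundance)
        axes.
    reference
        ``"auto"`` selects the reference by the 75th-percentile rule;
        otherwise the given sample id is used.

    Raises
    ------
    NormalizationError
        If a sample has all-zero counts (its library size is undefined).
    """
    x = counts.counts.astype(float)
    if counts.n_samples < 2:
        raise DesignError("TMM needs at least 2 samples")
    lib_sizes = x.sum(axis=0)
    zero = np.where(lib_sizes == 0)[0]
    if zero.size:
        raise NormalizationError(
            f"sample {counts.sample_ids[zero[0]]!r} has all-zero counts"
        )

    if reference == "auto":
        # 75th percentile of count fractions (scale-free, so CPM vs fraction
        # is immaterial); closest to the mean wins, first index breaks ties.
        f75 = np.quantile(x, 0.75, axis=0) / lib_sizes
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference not in counts.sample_ids:
            raise NormalizationError(f"reference sample {reference!r} not found")
        ref_idx = counts.sample_ids.index(reference)

    log2_factors = np.array(
        [
            _tmm_pair_factor(
                x[:, s],
                x[:, ref_idx],
                lib_sizes[s],
                lib_sizes[ref_idx],
                trim_m,
                trim_a,
                counts.sample_ids[s],
            )
            if s != ref_idx
            else 0.0
            for s in range(counts.n_samples)
        ]
    )
    factors = 2.0 ** log2_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1

    eff = lib_sizes * factors
    cpm = x / eff[np.newaxis, :] * 1e6
    return NormalizationResult(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        factors={s: float(f) for s, f in zip(counts.sample_ids, factors)},
        lib_sizes={s: int(n) for s, n in zip(counts.sample_ids, lib_sizes)},
        cpm=cpm,
        reference_sample=counts.sample_ids[ref_idx],
    )


def cpm_means_by_group(
    norm: NormalizationResult,
    groups: dict[str, str],
    control_label: str,
) -> pd.DataFrame:
    """Arithmetic per-gene CPM means within the control and treated groups.

    Returns a frame indexed by gene id with columns ``mean_cpm_control`` and
    ``mean_cpm_treated``.  No pseudocount is applied here; that happens only
    when a log fold-change is formed downstream.
    """
    missing = [s for s in norm.sample_ids if s not in groups]
    if missing:
        raise DesignError(f"samples without group labels: {missing}")
    is_treated = np.array([groups[s] != control_label for s in norm.sample_ids])
    if is_treated.all() or (~is_treated).all():
        raise DesignError("both groups must be represented among the samples")
    return pd.DataFrame(
        {
            "mean_cpm_control": norm.cpm[:, ~is_treated].mean(axis=1),
            "mean_cpm_treated": norm.cpm[:, is_treated].mean(axis=1),
        },
        index=pd.Index(norm.gene_ids, name="gene_id"),
    )
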