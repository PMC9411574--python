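"""The permutation-null DE procedure: statistics, scheme, null, p, calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permdeg import (
    DesignError,
    SimConfig,
    Thresholds,
    build_null,
    call_degs,
    derive_fc_cutoff,
    empirical_p,
    enumerate_assignments,
    fold_change,
    format_fold_change,
    log2fc,
    simulate_counts,
    t_statistic,
    t_statistics,
    tmm_factors,
)
from permdeg.permtest import NullDistribution, expression_filter


class TestTStatistic:
    def test_identical_constant_groups_give_zero(self):
        assert t_statistic([5, 5, 5], [5, 5, 5]) == 0.0

    def test_hand_computed_pooled_t(self):
        # pooled variance 1, difference 3 -> t = 3 / sqrt(2/3)
        assert t_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(
            3.0 / math.sqrt(2.0 / 3.0)
        )

    def test_zero_variance_nonzero_difference_is_signed_infinity(self):
        assert t_statistic([0, 0, 0], [7, 7, 7]) == np.inf
        assert t_statistic([7, 7, 7], [0, 0, 0]) == -np.inf

    def test_group_of_one_rejected(self):
        with pytest.raises(DesignError):
            t_statistic([1.0], [2.0, 3.0])

    def test_matches_scipy_on_generic_rows(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(5)
        ctl = rng.normal(size=(40, 3))
        trt = rng.normal(size=(40, 4))
        mine = t_statistics(ctl, trt)
        ref = ttest_ind(trt, ctl, axis=1).statistic
        np.testing.assert_allclose(mine, ref, rtol=1e-10)
        welch = t_statistics(ctl, trt, welch=True)
        ref_w = ttest_ind(trt, ctl, axis=1, equal_var=False).statistic
        np.testing.assert_allclose(welch, ref_w, rtol=1e-10)

    @given(
        x=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=6),
        y=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_label_swap_negates_t(self, x, y):
        t_fwd = t_statistic(x, y)
        t_rev = t_statistic(y, x)
        if math.isfinite(t_fwd):
            assert t_rev == pytest.approx(-t_fwd, abs=1e-8)
        else:
            assert t_rev == -t_fwd


class TestLog2fc:
    @pytest.mark.parametrize(
        "ctl, trt, pc, expected",
        [
            (10.0, 10.0, 0.5, 0.0),
            (0.0, 0.0, 0.5, 0.0),
            (4.5, 19.5, 0.5, 2.0),  # log2(20/5)
        ],
    )
    def test_examples(self, ctl, trt, pc, expected):
        assert log2fc(ctl, trt, pc) == pytest.approx(expected)

    @given(
        ctl=st.floats(0, 1e6),
        trt=st.floats(0, 1e6),
        pc=st.floats(1e-3, 10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_finite_and_antisymmetric(self, ctl, trt, pc):
        fwd = log2fc(ctl, trt, pc)
        assert math.isfinite(fwd)
        assert log2fc(trt, ctl, pc) == pytest.approx(-fwd, abs=1e-9)

    def test_fold_change_display(self):
        assert fold_change(1.0) == 2.0
        assert format_fold_change(0.428) == "1.35"


GROUPS_3V3 = {f"C{i}": "ctl" for i in range(3)} | {f"T{i}": "trt" for i in range(3)}
SAMPLES_3V3 = [f"C{i}" for i in range(3)] + [f"T{i}" for i in range(3)]


class TestEnumerateAssignments:
    @pytest.mark.parametrize(
        "n0, n1, expected",
        [(3, 3, 20), (2, 2, 6), (2, 3, 10)],
    )
    def test_exhaustive_counts(self, n0, n1, expected):
        samples = [f"C{i}" for i in range(n0)] + [f"T{i}" for i in range(n1)]
        groups = {s: ("ctl" if s.startswith("C") else "trt") for s in samples}
        scheme = enumerate_assignments(groups, samples, "ctl")
        assert scheme.n_assignments == expected
        assert scheme.exhaustive
        # all distinct, all preserve group sizes, observed first
        rows = {tuple(r) for r in scheme.assignments}
        assert len(rows) == expected
        assert np.all(scheme.assignments.sum(axis=1) == n1)
        np.testing.assert_array_equal(
            scheme.observed, [s.startswith("T") for s in samples]
        )

    def test_cap_is_deterministic_and_keeps_observed_first(self):
        a = enumerate_assignments(GROUPS_3V3, SAMPLES_3V3, "ctl", cap=5, seed=3)
        b = enumerate_assignments(GROUPS_3V3, SAMPLES_3V3, "ctl", cap=5, seed=3)
        assert a.n_assignments == 5
        assert not a.exhaustive
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.observed, b.observed)
        assert len({tuple(r) for r in a.assignments}) == 5

    def test_brute_force_label_vector_equivalence(self):
        """Exhaustive enumeration equals dedup of all n! label orderings."""
        for n0, n1 in [(2, 2), (2, 3), (3, 3)]:
            samples = list(range(n0 + n1))
            labels = ["ctl"] * n0 + ["trt"] * n1
            brute = {
                tuple(lab == "trt" for lab in perm)
                for perm in itertools.permutations(labels)
            }
            groups = {s: lab for s, lab in zip(samples, labels)}
            scheme = enumerate_assignments(groups, samples, "ctl")
            assert {tuple(r) for r in scheme.assignments} == brute


def _norm_for(cpm: np.ndarray):
    from permdeg.normalization import NormalizationResult

    n_samples = cpm.shape[1]
    sids = SAMPLES_3V3[:n_samples]
    return NormalizationResult(
        gene_ids=[f"G{i}" for i in range(cpm.shape[0])],
        sample_ids=sids,
        factors={s: 1.0 for s in sids},
        lib_sizes={s: 10**6 for s in sids},
        cpm=np.asarray(cpm, dtype=float),
        reference_sample=sids[0],
    )


class TestBuildNull:
    def test_null_sizes_3v3(self):
        rng = np.random.default_rng(0)
        norm = _norm_for(rng.gamma(2.0, 50.0, size=(100, 6)))
        scheme = enumerate_assignments(GROUPS_3V3, SAMPLES_3V3, "ctl")
        null = build_null(norm, scheme, Thresholds())
        assert null.null_t.size == 100 * 19
        assert null.null_log2fc.size == 100 * 19
        assert np.all(np.isfinite(null.null_log2fc))

    def test_null_sizes_single_gene_2v2(self):
        rng = np.random.default_rng(1)
        samples = ["C0", "C1", "T0", "T1"]
        groups = {"C0": "ctl", "C1": "ctl", "T0": "trt", "T1": "trt"}
        norm = _norm_for(rng.gamma(2.0, 50.0, size=(1, 4)))
        scheme = enumerate_assignments(groups, samples, "ctl")
        null = build_null(norm, scheme, Thresholds())
        assert null.null_t.size == 5

    def test_degenerate_scheme_rejected(self):
        norm = _norm_for(np.ones((3, 6)))
        scheme = enumerate_assignments(GROUPS_3V3, SAMPLES_3V3, "ctl")
        scheme.assignments = scheme.assignments[:1]
        with pytest.raises(DesignError):
            build_null(norm, scheme, Thresholds())

    def test_exchangeable_data_observed_t_within_null_range(self):
        rng = np.random.default_rng(42)
        cpm = rng.gamma(2.0, 50.0, size=(300, 6))
        norm = _norm_for(cpm)
        scheme = enumerate_assignments(GROUPS_3V3, SAMPLES_3V3, "ctl")
        null = build_null(norm, scheme, Thresholds())
        obs = t_statistics(cpm[:, :3], cpm[:, 3:])
        # no systematic excess of the observed statistics over the null
        assert np.abs(obs).max() <= np.abs(null.null_t).max() * 1.5
        assert np.median(np.abs(obs)) == pytest.approx(
            np.median(np.abs(null.null_t)), rel=0.25
        )

    def test_complement_assignments_give_equal_magnitude_t(self):
        """Complementary label splits negate t, so |t| values pair up."""
        rng = np.random.default_rng(3)
        cpm = rng.gamma(2.0, 50.0, size=(5, 6))
        norm = _norm_for(cpm)
        scheme = enumerate_assignments(GROUPS_3V3, SAMPLES_3V3, "ctl")
        null_t = build_null(norm, scheme, Thresholds()).null_t.reshape(19, 5)
        masks = [tuple(m) for m in scheme.assignments[1:]]
        for i, m in enumerate(masks):
            comp = tuple(not v for v in m)
            if comp in masks:
                j = masks.index(comp)
                np.testing.assert_allclose(null_t[i], -null_t[j], rtol=1e-10)


class TestEmpiricalP:
    def test_hand_counted_example(self):
        null = NullDistribution(
            null_t=np.array([0.1, -0.2, 0.3]),
            null_log2fc=np.zeros(3),
            n_assignments_used=4,
        )
        assert empirical_p(np.array([0.25]), null)[0] == pytest.approx(0.5)

    def test_zero_t_has_p_one(self):
        null = NullDistribution(
            null_t=np.array([0.1, -0.2, 0.3]),
            null_log2fc=np.zeros(3),
            n_assignments_used=4,
        )
        assert empirical_p(np.array([0.0]), null)[0] == 1.0

    def test_add_one_minimum(self):
        null = NullDistribution(
            null_t=np.arange(1, 20, dtype=float),
            null_log2fc=np.zeros(19),
            n_assignments_used=20,
        )
        assert empirical_p(np.array([100.0]), null)[0] == pytest.approx(1 / 20)

    def test_infinity_handling(self):
        null = NullDistribution(
            null_t=np.array([0.5, np.inf, -np.inf]),
            null_log2fc=np.zeros(3),
            n_assignments_used=4,
        )
        # finite observed: all three null values at least as extreme as 0.4
        assert empirical_p(np.array([0.4]), null)[0] == 1.0
        # observed infinity ties with the two null infinities
        assert empirical_p(np.array([np.inf]), null)[0] == pytest.approx(3 / 4)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=50),
        st.lists(st.floats(-50, 50), min_size=2, max_size=30),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_abs_t_and_bounded(self, obs, null_vals):
        null = NullDistribution(
            null_t=np.array(null_vals),
            null_log2fc=np.zeros(len(null_vals)),
            n_assignments_used=len(null_vals) + 1,
        )
        p = empirical_p(np.array(obs), null)
        assert np.all(p > 0) and np.all(p <= 1)
        order = np.argsort(np.abs(obs))
        assert np.all(np.diff(p[order]) <= 1e-15)


class TestDeriveFcCutoff:
    def test_evenly_spaced_null(self):
        null = NullDistribution(
            null_t=np.zeros(1001),
            null_log2fc=np.linspace(-1, 1, 1001),
            n_assignments_used=2,
        )
        th = Thresholds()
        assert derive_fc_cutoff(null, th) == pytest.approx(0.99)
        assert th.log2fc_cutoff == pytest.approx(0.99)

    def test_all_zero_null(self):
        null = NullDistribution(
            null_t=np.zeros(10), null_log2fc=np.zeros(10), n_assignments_used=2
        )
        assert derive_fc_cutoff(null, Thresholds()) == 0.0

    def test_matches_brute_force_percentile_rule(self):
        """Oracle: direct linear-interpolation percentile on sorted values."""

        def brute_percentile(values, q):
            a = sorted(values)
            h = (len(a) - 1) * q / 100.0
            lo = math.floor(h)
            hi = min(lo + 1, len(a) - 1)
            return a[lo] + (h - lo) * (a[hi] - a[lo])

        vals = [-0.6, -0.2, 0.0, 0.2, 0.4]
        null = NullDistribution(
            null_t=np.zeros(5),
            null_log2fc=np.array(vals),
            n_assignments_used=2,
        )
        expected = (
            abs(brute_percentile(vals, 0.5)) + abs(brute_percentile(vals, 99.5))
        ) / 2.0
        assert derive_fc_cutoff(null, Thresholds()) == pytest.approx(
            expected, abs=1e-12
        )


class TestCallDegs:
    def _run(self, seed=7, **sim_kwargs):
        cm, truth = simulate_counts(SimConfig(seed=seed, **sim_kwargs))
        norm = tmm_factors(cm)
        table = call_degs(norm, cm.groups, cm.control_label)
        return cm, truth, norm, table

    def test_null_matrix_p_fraction_near_alpha(self):
        _, _, _, table = self._run(n_genes=2000, de_fraction=0.0)
        kept = ~table["filtered"]
        frac = (table.loc[kept, "p_adj"] <= 0.05).mean()
        assert frac <= 0.07

    def test_extreme_gene_is_called_up(self):
        """A gene with a ~64-fold separation must survive any derived cutoff."""
        cm, _, _, _ = self._run(n_genes=2000, de_fraction=0.0)
        counts = cm.counts.copy()
        counts[0, :3] = [1, 1, 1]
        counts[0, 3:] = [64, 64, 64]
        from permdeg import CountMatrix

        cm2 = CountMatrix(cm.gene_ids, cm.sample_ids, counts, cm.groups, cm.control_label)
        norm = tmm_factors(cm2)
        table = call_degs(norm, cm2.groups, cm2.control_label)
        assert table.loc[table["gene_id"] == cm.gene_ids[0], "call"].iloc[0] == "up"

    def test_alpha_zero_calls_nothing(self):
        cm, _, norm, _ = self._run(n_genes=500, de_fraction=0.05)
        table = call_degs(norm, cm.groups, cm.control_label, Thresholds(alpha=0.0))
        assert (table["call"] == "none").all()

    def test_call_invariant(self):
        _, _, _, table = self._run(n_genes=800, de_fraction=0.05)
        cutoff = table.attrs["log2fc_cutoff"]
        alpha = table.attrs["alpha"]
        up = (
            ~table["filtered"]
            & (table["p_adj"] <= alpha)
            & (table["log2fc"] > cutoff)
        )
        down = (
            ~table["filtered"]
            & (table["p_adj"] <= alpha)
            & (table["log2fc"] < -cutoff)
        )
        assert ((table["call"] == "up") == up).all()
        assert ((table["call"] == "down") == down).all()
        assert (table.loc[table["filtered"], "call"] == "none").all()

    def test_label_swap_antisymmetry(self):
        """Swapping which group is 'control' negates t and log2FC, keeps
        p_adj, and exchanges up/down calls."""
        cm, _, norm, _ = self._run(n_genes=600, de_fraction=0.05)
        fwd = call_degs(norm, cm.groups, cm.control_label)
        rev = call_degs(norm, cm.groups, cm.treated_label)
        np.testing.assert_allclose(
            rev["log2fc"], -fwd["log2fc"], rtol=0, atol=1e-10
        )
        finite = np.isfinite(fwd["t_stat"])
        np.testing.assert_allclose(
            rev.loc[finite, "t_stat"], -fwd.loc[finite, "t_stat"], atol=1e-8
        )
        np.testing.assert_allclose(rev["p_adj"], fwd["p_adj"], rtol=1e-12)
        swap = {"up": "down", "down": "up", "none": "none"}
        assert rev["call"].tolist() == [swap[c] for c in fwd["call"]]

    def test_filter_disabled_keeps_everything(self):
        cm, _, norm, _ = self._run(n_genes=400, de_fraction=0.0)
        th = Thresholds(filter_enabled=False)
        keep = expression_filter(norm, cm.groups, cm.control_label, th)
        assert keep.all()
        table = call_degs(norm, cm.groups, cm.control_label, th)
        assert not table["filtered"].any()

    def test_bh_option_is_more_conservative(self):
        cm, _, norm, _ = self._run(n_genes=600, de_fraction=0.05)
        plain = call_degs(norm, cm.groups, cm.control_label, Thresholds())
        bh = call_degs(norm, cm.groups, cm.control_label, Thresholds(bh=True))
        assert np.all(bh["p_adj"] >= plain["p_adj"] - 1e-12)
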