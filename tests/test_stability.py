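import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab import (
    CtValidationError,
    SampleSet,
    bestkeeper,
    delta_ct_method,
    genorm,
    normfinder,
    to_relative_quantities,
)

import _oracles as oracle
from conftest import make_matrix


def random_matrix(seed, k=4, n=6, lo=16.0, hi=32.0):
    r = np.random.default_rng(seed)
    return make_matrix(r.uniform(lo, hi, size=(k, n)))


# ---------------------------------------------------------------------------
# comparative delta-Ct


class TestDeltaCt:
    def test_worked_example(self, toy_matrix):
        res = delta_ct_method(toy_matrix)
        i = {g: idx for idx, g in enumerate(res.genes)}
        assert res.pairwise_sd[i["A"], i["B"]] == pytest.approx(1.0, abs=1e-4)
        assert res.pairwise_sd[i["A"], i["C"]] == pytest.approx(0.5774, abs=1e-4)
        assert res.pairwise_sd[i["B"], i["C"]] == pytest.approx(0.5774, abs=1e-4)
        assert res.score["A"] == pytest.approx(0.7887, abs=1e-4)
        assert res.score["B"] == pytest.approx(0.7887, abs=1e-4)
        assert res.score["C"] == pytest.approx(0.5774, abs=1e-4)
        assert res.rank["C"] == 1.0
        # A and B tie: average ranks
        assert res.rank["A"] == res.rank["B"] == 2.5

    def test_parallel_profiles_have_zero_pairwise_sd(self):
        m = make_matrix([[20, 21, 22], [23, 24, 25], [30, 31, 33]])
        res = delta_ct_method(m)
        assert res.pairwise_sd[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_shift_invariance(self):
        m = random_matrix(7)
        base = delta_ct_method(m)
        shifted = m.ct.copy()
        shifted[:, 1] += 1.7
        res = delta_ct_method(make_matrix(shifted))
        assert res.score == pytest.approx(base.score)
        assert res.rank == base.rank

    def test_needs_three_genes_and_samples(self):
        with pytest.raises(CtValidationError):
            delta_ct_method(make_matrix([[20, 21, 22], [23, 24, 25]]))
        with pytest.raises(CtValidationError):
            delta_ct_method(make_matrix([[20, 21], [23, 24], [30, 31]]))


# ---------------------------------------------------------------------------
# geNorm


class TestGeNorm:
    def test_full_set_M_equals_delta_ct_scores_on_toy(self, toy_matrix):
        res = genorm(toy_matrix)
        assert res.full_set_M["A"] == pytest.approx(0.7887, abs=1e-4)
        assert res.full_set_M["B"] == pytest.approx(0.7887, abs=1e-4)
        assert res.full_set_M["C"] == pytest.approx(0.5774, abs=1e-4)

    def test_proportional_profiles_give_zero_M_and_V(self):
        # all genes exact scalar multiples of one expression profile:
        # constant Ct offsets per gene
        base = np.array([20.0, 21.0, 19.5, 22.0])
        m = make_matrix(np.vstack([base, base + 2, base + 5]))
        res = genorm(m)
        assert all(v == pytest.approx(0, abs=1e-12) for v in res.full_set_M.values())
        assert all(v == pytest.approx(0, abs=1e-12) for _, v in res.v_series)

    def test_v_series_length_is_k_minus_2(self):
        res3 = genorm(random_matrix(1, k=3))
        assert [n for n, _ in res3.v_series] == [2]
        res6 = genorm(random_matrix(2, k=6))
        assert [n for n, _ in res6.v_series] == [2, 3, 4, 5]

    def test_stepwise_rank_is_reverse_removal_order(self):
        res = genorm(random_matrix(3, k=5))
        ordering = sorted(res.genes, key=lambda g: res.rank[g])
        assert ordering[:2] == list(res.retained_pair)
        assert ordering[2:] == res.removal_order[::-1]
        assert len(res.removal_order) == 3

    def test_full_set_M_is_rowmean_of_pairwise_V(self):
        res = genorm(random_matrix(4, k=5))
        k = len(res.genes)
        expected = res.pairwise_V.sum(axis=1) / (k - 1)
        got = np.array([res.full_set_M[g] for g in res.genes])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_rejects_nonpositive_quantities(self):
        from refstab.ct_model import RelativeQuantities

        with pytest.raises(Exception):
            q = RelativeQuantities(
                ["a", "b", "c"], ["s1", "s2", "s3"],
                np.array([[1, 0.5, -0.1]] * 3), {"a": 2, "b": 2, "c": 2},
            )
            genorm(q)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_genorm_full_set_equals_delta_ct_at_perfect_doubling(seed):
    """With per-cycle fold 2 the geNorm M value and the delta-Ct score are
    the same statistic: log2 ratios of quantities are Ct differences."""
    m = random_matrix(seed, k=5, n=7)
    dct = delta_ct_method(m)
    gn = genorm(to_relative_quantities(m, 2.0))
    for g in m.genes:
        assert abs(dct.score[g] - gn.full_set_M[g]) <= 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_per_gene_shift_invariance_of_ratio_methods(seed):
    """Adding a constant to one gene's Ct everywhere does not change
    delta-Ct, geNorm or NormFinder scores, nor BestKeeper's sd_mad — only
    BestKeeper's CV% moves (its denominator is the mean Ct)."""
    m = random_matrix(seed, k=4, n=8)
    shifted = m.ct.copy()
    shifted[1] += 2.9
    m2 = make_matrix(shifted)
    assert delta_ct_method(m2).score == pytest.approx(delta_ct_method(m).score, abs=1e-9)
    g1, g2 = genorm(m), genorm(m2)
    assert g2.full_set_M == pytest.approx(g1.full_set_M, abs=1e-9)
    n1, n2 = normfinder(m, mode="ungrouped"), normfinder(m2, mode="ungrouped")
    assert n2.stability == pytest.approx(n1.stability, abs=1e-9)
    b1, b2 = bestkeeper(m), bestkeeper(m2)
    assert b2.sd_mad == pytest.approx(b1.sd_mad, abs=1e-9)
    assert b2.cv_percent["g2"] != pytest.approx(b1.cv_percent["g2"], abs=1e-6)


def test_bestkeeper_is_sensitive_to_per_sample_shifts():
    # flat profiles: every gene has zero dispersion before the shift
    m = make_matrix(np.repeat(np.array([20.0, 22.0, 24.0, 26.0])[:, None], 8, axis=1))
    shifts = np.linspace(-1.5, 1.5, 8)
    m2 = make_matrix(m.ct + shifts[None, :])
    b1, b2 = bestkeeper(m), bestkeeper(m2)
    assert all(b2.sd_mad[g] > b1.sd_mad[g] for g in m.genes)
    # while the ratio methods do not move
    assert delta_ct_method(m2).score == pytest.approx(delta_ct_method(m).score, abs=1e-9)
    assert genorm(m2).full_set_M == pytest.approx(genorm(m).full_set_M, abs=1e-9)


# ---------------------------------------------------------------------------
# NormFinder


class TestNormFinder:
    def test_model_perfect_data_gives_zero_stability(self):
        alpha = np.array([1.0, -2.0, 0.5, 3.0])
        beta = np.array([0.1, 0.5, -0.3, 0.2, 0.9])
        m = make_matrix(-(alpha[:, None] + beta[None, :]))
        res = normfinder(m, mode="ungrouped")
        assert all(v == pytest.approx(0, abs=1e-9) for v in res.stability.values())

    def test_planted_variances_recovered_in_order(self):
        r = np.random.default_rng(5)
        sig = np.array([0.05, 0.05, 0.5, 1.0])
        n = 300
        y = r.normal(size=(1, n)) + sig[:, None] * r.normal(size=(4, n))
        res = normfinder(make_matrix(-y), mode="ungrouped")
        vals = [res.stability[g] for g in res.genes]
        assert vals[0] < vals[2] < vals[3]
        assert vals[1] < vals[2]

    def test_grouped_shift_detected_and_deviations_sum_to_zero(self):
        k, per = 4, 5
        ct = np.full((k, 2 * per), 20.0) + np.arange(k)[:, None]
        ct[0, per:] -= 1.0  # gene 1 is 1 cycle brighter (+1 log2) in group 2
        samples = [f"s{j}" for j in range(2 * per)]
        ss = SampleSet(
            "two_groups", samples,
            groups={s: ("grp1" if j < per else "grp2") for j, s in enumerate(samples)},
        )
        m = make_matrix(ct, samples=samples)
        res = normfinder(m, ss, mode="grouped")
        # per-sample centering spreads the shift: the shifted gene keeps
        # (1 - 1/k) of it, split +/- around its overall mean
        d_expected = (1 - 1 / k) / 2
        assert abs(res.inter_group_deviation[("g1", "grp2")]) == pytest.approx(
            d_expected, abs=1e-9
        )
        assert res.stability["g1"] == pytest.approx(d_expected, abs=1e-9)
        for grp in ("grp1", "grp2"):
            total = sum(res.inter_group_deviation[(g, grp)] for g in res.genes)
            assert total == pytest.approx(0, abs=1e-9)
        others = [res.stability[g] for g in res.genes if g != "g1"]
        assert all(v < res.stability["g1"] for v in others)

    def test_grouped_requires_two_per_group(self):
        m = random_matrix(1, k=3, n=4)
        ss = SampleSet(
            "x", m.samples,
            groups={m.samples[0]: "g1", m.samples[1]: "g1",
                    m.samples[2]: "g1", m.samples[3]: "g2"},
        )
        with pytest.raises(CtValidationError, match="fewer than 2"):
            normfinder(m, ss, mode="grouped")

    def test_auto_mode_follows_group_labels(self):
        m = random_matrix(2, k=3, n=6)
        plain = SampleSet("plain", m.samples)
        grouped = SampleSet(
            "grp", m.samples,
            groups={s: ("g1" if j < 3 else "g2") for j, s in enumerate(m.samples)},
        )
        assert normfinder(m, plain).mode == "ungrouped"
        assert normfinder(m, grouped).mode == "grouped"

    def test_matches_ml_variance_components_oracle(self):
        """Moment estimates agree with a direct ML fit on small instances."""
        ratios = []
        for seed in range(12):
            r = np.random.default_rng(100 + seed)
            sig = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
            ct = -(r.normal(size=(1, 6)) + sig[:, None] * r.normal(size=(5, 6)))
            mine = np.array(
                list(normfinder(make_matrix(ct), mode="ungrouped").stability.values())
            )
            ml = np.sqrt(oracle.ml_variance_components(np.asarray(ct)))
            keep = ml > 1e-3
            ratios.extend((mine[keep] / ml[keep]).tolist())
        assert abs(np.median(ratios) - 1.0) < 0.10


# ---------------------------------------------------------------------------
# BestKeeper


class TestBestKeeper:
    def test_constant_series(self):
        m = make_matrix([[20, 20, 20, 20], [25, 26, 27, 28.0]])
        res = bestkeeper(m)
        g = res.genes[0]
        assert res.sd_mad[g] == 0 and res.cv_percent[g] == 0
        assert res.arithmetic_mean_ct[g] == pytest.approx(20, abs=1e-12)
        assert res.geometric_mean_ct[g] == pytest.approx(20, abs=1e-9)

    def test_hand_arithmetic(self):
        m = make_matrix([[19, 21, 20, 20], [25, 26, 27, 28.0]])
        res = bestkeeper(m)
        g = res.genes[0]
        assert res.arithmetic_mean_ct[g] == pytest.approx(20)
        assert res.sd_mad[g] == pytest.approx(0.5)
        assert res.cv_percent[g] == pytest.approx(2.5)

    def test_duplicate_genes_tie(self):
        m = make_matrix([[19, 21, 20], [19, 21, 20], [25, 27, 29.0]])
        res = bestkeeper(m)
        assert res.sd_mad[res.genes[0]] == res.sd_mad[res.genes[1]]
        assert res.rank[res.genes[0]] == res.rank[res.genes[1]] == 1.5

    def test_ordering_invariants(self):
        m = random_matrix(9, k=5, n=10)
        res = bestkeeper(m)
        for g in res.genes:
            assert (
                res.min_ct[g]
                <= res.geometric_mean_ct[g]
                <= res.arithmetic_mean_ct[g]
                <= res.max_ct[g]
            )

    def test_index_correlation_bounds(self):
        res = bestkeeper(random_matrix(10, k=4, n=8), with_index=True)
        for v in res.index_correlation.values():
            assert -1 - 1e-9 <= v <= 1 + 1e-9

    def test_cv_ranking_key(self):
        m = make_matrix([[10, 11], [40, 41.0], [20, 22]])
        by_sd = bestkeeper(m, ranking_key="sd_mad")
        by_cv = bestkeeper(m, ranking_key="cv_percent")
        # same sd_mad for rows 1-2 but very different means: CV reorders
        assert by_sd.rank != by_cv.rank


# ---------------------------------------------------------------------------
# brute-force oracle equality


def test_exhaustive_small_grid_matches_oracles():
    """Every 3x3 matrix over the {20, 23} Ct grid: delta-Ct, geNorm and
    BestKeeper agree with loop-based implementations of the formulas."""
    vals = (20.0, 23.0)
    checked = 0
    for cells in itertools.product(vals, repeat=9):
        ct = np.array(cells).reshape(3, 3)
        m = make_matrix(ct)
        rows = ct.tolist()

        dct = delta_ct_method(m)
        expected = oracle.brute_delta_ct_scores(rows)
        got = [dct.score[g] for g in m.genes]
        np.testing.assert_allclose(got, expected, atol=1e-12)

        q = to_relative_quantities(m, 2.0)
        gn = genorm(q)
        q_rows = q.q.tolist()
        np.testing.assert_allclose(
            [gn.full_set_M[g] for g in m.genes],
            oracle.brute_genorm_full_M(q_rows),
            atol=1e-9,
        )

        bk = bestkeeper(m, with_index=False)
        for i, g in enumerate(m.genes):
            ref = oracle.brute_bestkeeper(rows[i])
            assert bk.sd_mad[g] == pytest.approx(ref["sd_mad"], abs=1e-12)
            assert bk.cv_percent[g] == pytest.approx(ref["cv_percent"], abs=1e-12)
            assert bk.geometric_mean_ct[g] == pytest.approx(ref["gm"], abs=1e-9)
        checked += 1
    assert checked == 2**9


def test_normfinder_matches_loop_oracle_on_random_integer_matrices():
    r = np.random.default_rng(42)
    for _ in range(200):
        ct = r.integers(18, 26, size=(3, 4)).astype(float)
        # skip degenerate all-equal columns handled by flooring anyway
        res = normfinder(make_matrix(ct), mode="ungrouped")
        expected = np.sqrt(oracle.brute_normfinder_sigma(ct.tolist()))
        got = np.array([res.stability[g] for g in res.genes])
        np.testing.assert_allclose(got, expected, atol=1e-10)
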