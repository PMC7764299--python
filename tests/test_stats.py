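"""Statistical layer: size factors, NB Wald, BH, DEU, differential IR,
Mann-Whitney — each against an independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from intronret.stats import (
    bh_adjust,
    deu_usage,
    differential_exon_usage,
    differential_ir,
    mann_whitney_u,
    nb_wald_test,
    size_factors,
)

RNG = np.random.default_rng(20240915)


def bh_oracle(p):
    """Textbook step-up BH with monotonicity enforcement."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestSizeFactors:
    def _matrix(self, arr, samples):
        return pd.DataFrame(arr, columns=samples)

    def test_identical_samples_unit_factors(self):
        mat = self._matrix(np.tile([[10], [20], [30]], (1, 2)), ["a", "b"])
        np.testing.assert_allclose(size_factors(mat), [1.0, 1.0])

    def test_doubled_sample_scales_two_to_one(self):
        base = np.array([[10], [20], [30]])
        mat = self._matrix(np.hstack([base, 2 * base]), ["a", "b"])
        f = size_factors(mat)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_matches_definition_on_random_matrix(self):
        counts = RNG.negative_binomial(10, 0.1, size=(50, 4)) + 1
        mat = self._matrix(counts, list("abcd"))
        f = size_factors(mat)
        # direct re-computation per definition
        log_geo = np.mean(np.log(counts), axis=1)
        expected = [
            np.exp(np.median(np.log(counts[:, j]) - log_geo))
            for j in range(4)
        ]
        np.testing.assert_allclose(f.to_numpy(), expected)

    def test_fallback_when_no_common_feature(self):
        mat = self._matrix(np.array([[5, 0], [0, 5]]), ["a", "b"])
        f = size_factors(mat)
        assert (f > 0).all()


class TestNBWald:
    def _null_matrix(self, n_features, n=6, mu=100, alpha=0.1, rng=None):
        rng = rng or RNG
        counts = rng.negative_binomial(
            1 / alpha, 1 / (1 + alpha * mu), size=(n_features, 2 * n)
        )
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        return pd.DataFrame(counts, columns=cols), pd.Series(
            ["A"] * n + ["B"] * n, index=cols
        )

    def test_null_type_one_error_calibrated(self):
        counts, groups = self._null_matrix(2000, rng=np.random.default_rng(5))
        res = nb_wald_test(counts, groups)
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_equal_group_means_fc_near_zero(self):
        counts, groups = self._null_matrix(500, rng=np.random.default_rng(6))
        res = nb_wald_test(counts, groups)
        assert abs(res["log2_fc"].mean()) < 0.05

    def test_planted_fold_change_detected(self):
        # symmetric planting (up and down) keeps median-of-ratios centred
        rng = np.random.default_rng(7)
        n = 6
        null = rng.negative_binomial(10, 1 / (1 + 0.1 * 100), size=(400, 2 * n))
        up_a = rng.negative_binomial(10, 1 / (1 + 0.1 * 400), size=(50, n))
        up_b = rng.negative_binomial(10, 1 / (1 + 0.1 * 100), size=(50, n))
        dn_a = rng.negative_binomial(10, 1 / (1 + 0.1 * 100), size=(50, n))
        dn_b = rng.negative_binomial(10, 1 / (1 + 0.1 * 400), size=(50, n))
        counts = np.vstack(
            [null, np.hstack([up_a, up_b]), np.hstack([dn_a, dn_b])]
        )
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        mat = pd.DataFrame(counts, columns=cols)
        groups = pd.Series(["A"] * n + ["B"] * n, index=cols)
        res = nb_wald_test(mat, groups)
        planted = res.iloc[400:]
        assert (planted["q_value"] < 0.05).mean() >= 0.9
        assert planted.iloc[:50]["log2_fc"].mean() == pytest.approx(2.0, abs=0.2)
        assert planted.iloc[50:]["log2_fc"].mean() == pytest.approx(-2.0, abs=0.2)

    def test_all_zero_feature_flagged(self):
        counts, groups = self._null_matrix(10, rng=np.random.default_rng(8))
        counts.iloc[0] = 0
        res = nb_wald_test(counts, groups)
        assert res.loc[0, "flagged"]
        assert res.loc[0, "p_value"] == 1.0 and res.loc[0, "log2_fc"] == 0.0

    def test_column_order_invariance(self):
        # shuffle columns, keeping a group-A column first so the level
        # order (first-named group) is unchanged
        counts, groups = self._null_matrix(50, rng=np.random.default_rng(9))
        perm = ["a0"] + list(np.random.default_rng(1).permutation(
            [c for c in counts.columns if c != "a0"]
        ))
        res1 = nb_wald_test(counts, groups)
        res2 = nb_wald_test(counts[perm], groups[perm])
        np.testing.assert_allclose(res1["stat"], res2["stat"], rtol=1e-10)


class TestDifferentialIR:
    def _cohort(self, r_a, r_b, n=6, evidence=200, rng=None, n_introns=40):
        rng = rng or np.random.default_rng(11)
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        total = rng.poisson(evidence, size=(n_introns, 2 * n))
        r = np.concatenate([np.full(n, r_a), np.full(n, r_b)])
        intronic = rng.binomial(total, r[None, :])
        junction = total - intronic
        idx = [f"i{k}" for k in range(n_introns)]
        groups = pd.Series(["A"] * n + ["B"] * n, index=cols)
        return (
            pd.DataFrame(intronic, index=idx, columns=cols),
            pd.DataFrame(junction, index=idx, columns=cols),
            groups,
        )

    def test_planted_delta_recovered(self):
        intr, junc, groups = self._cohort(0.3, 0.1)
        res = differential_ir(intr, junc, groups)
        assert (res["q_value"] < 0.05).mean() >= 0.9
        assert res["delta_ir"].mean() == pytest.approx(0.2, abs=0.02)

    def test_identical_groups_zero_delta(self):
        intr, junc, groups = self._cohort(0.2, 0.2, rng=np.random.default_rng(12))
        half = intr.shape[1] // 2
        intr.iloc[:, half:] = intr.iloc[:, :half].to_numpy()
        junc.iloc[:, half:] = junc.iloc[:, :half].to_numpy()
        res = differential_ir(intr, junc, groups)
        np.testing.assert_allclose(res["delta_ir"], 0.0, atol=1e-12)

    def test_null_fdr_control(self):
        intr, junc, groups = self._cohort(
            0.2, 0.2, n_introns=400, rng=np.random.default_rng(13)
        )
        res = differential_ir(intr, junc, groups)
        assert (res["q_value"] < 0.05).mean() <= 0.05

    def test_sign_agreement_for_significant(self):
        intr, junc, groups = self._cohort(0.3, 0.1, rng=np.random.default_rng(14))
        res = differential_ir(intr, junc, groups)
        sig = res[res["q_value"] < 0.05]
        assert (np.sign(sig["delta_ir"]) == np.sign(sig["log2_fc"])).all()

    def test_zero_evidence_group_excluded_from_family(self):
        intr, junc, groups = self._cohort(0.3, 0.1, rng=np.random.default_rng(15))
        intr.iloc[0, :6] = 0
        junc.iloc[0, :6] = 0
        res = differential_ir(intr, junc, groups)
        assert res.loc[0, "flagged"]
        assert np.isnan(res.loc[0, "q_value"])


class TestDEU:
    @pytest.mark.parametrize(
        "with_exon,without,expected",
        [(0, 5, 0.0), (3, 1, 0.75), (7, 13, 0.35), (5, 0, 1.0)],
    )
    def test_usage_exact(self, with_exon, without, expected):
        assert deu_usage(with_exon, without) == expected

    def test_usage_undefined(self):
        with pytest.raises(ValueError):
            deu_usage(0, 0)

    def _cohort(self, usage_a, usage_b, n=6, gene_mean=300, rng=None):
        rng = rng or np.random.default_rng(21)
        cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        gene = rng.poisson(gene_mean, size=(30, 2 * n))
        u = np.concatenate([np.full(n, usage_a), np.full(n, usage_b)])
        exon = rng.binomial(gene, u[None, :])
        idx = [f"e{k}" for k in range(30)]
        mapping = pd.Series([f"g{k}" for k in range(30)], index=idx)
        gmat = pd.DataFrame(gene, index=mapping.to_numpy(), columns=cols)
        emat = pd.DataFrame(exon, index=idx, columns=cols)
        groups = pd.Series(["A"] * n + ["B"] * n, index=cols)
        return emat, gmat, mapping, groups

    def test_null_usage_uniform_p(self):
        emat, gmat, mapping, groups = self._cohort(0.5, 0.5)
        res = differential_exon_usage(emat, gmat, mapping, groups)
        assert (res["p_value"] < 0.05).mean() <= 0.15
        assert (res["direction"] != "none").sum() >= 0  # directions defined

    def test_planted_usage_increase_up(self):
        emat, gmat, mapping, groups = self._cohort(0.8, 0.4)
        res = differential_exon_usage(emat, gmat, mapping, groups)
        sig = res[res["q_value"] < 0.05]
        assert len(sig) >= 25
        assert (sig["direction"] == "up").all()

    def test_constitutive_exon_no_call(self):
        emat, gmat, mapping, groups = self._cohort(0.5, 0.5)
        emat.iloc[0] = gmat.iloc[0].to_numpy()
        res = differential_exon_usage(emat, gmat, mapping, groups)
        assert res.loc[0, "direction"] == "none"
        assert res.loc[0, "p_value"] == 1.0

    def test_exon_exceeding_gene_rejected(self):
        emat, gmat, mapping, groups = self._cohort(0.5, 0.5)
        emat.iloc[0, 0] = gmat.iloc[0, 0] + 1
        with pytest.raises(ValueError, match="e0"):
            differential_exon_usage(emat, gmat, mapping, groups)


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_oracle_exhaustive_small_n(self):
        """Step-up oracle agreement on a grid of all p-vectors, n <= 6."""
        grid = [0.0, 0.01, 0.04, 0.2, 0.5, 1.0]
        for n in (1, 2, 3):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), bh_oracle(list(combo)), atol=1e-12
                )
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(4, 7))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_q_at_least_p_over_m_and_monotone(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) / len(p) - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_multisets(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 8.0  # n*m/2
        assert p > 0.5

    def test_matches_exhaustive_enumeration_4v4(self):
        """Exact p equals brute-force enumeration of all C(8,4) labelings."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            data = rng.normal(size=8)
            a, b = data[:4], data[4:]
            u_obs, p_obs = mann_whitney_u(a, b)
            # oracle: all assignments of the pooled values to group A
            us = []
            for combo in itertools.combinations(range(8), 4):
                ga = data[list(combo)]
                gb = data[[i for i in range(8) if i not in combo]]
                u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
                us.append(u)
            us = np.array(us)
            mean_u = 8.0
            p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
            assert p_obs == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
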