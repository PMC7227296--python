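"""Two-part model parts, min-p assembly, permutation calibration and FDR."""

import numpy as np
import pytest
from scipy import stats as sps

from micropart import (
    CountTable,
    TwoPartConfig,
    bh_fdr,
    binary_test,
    meta_combine,
    quantitative_test,
    run_two_part,
    two_part_single,
)
from micropart.association import permutation_correct, prepare_two_part, two_part_stats


class TestBinaryTest:
    def test_matches_pooled_t_test(self):
        y = np.array([1.0, 2, 3, 4, 5, 6])
        presence = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        beta1, z_b, p_b = binary_test(y, presence)
        assert beta1 == pytest.approx(3.0)
        t_oracle = sps.ttest_ind(y[presence], y[~presence], equal_var=True)
        assert p_b == pytest.approx(t_oracle.pvalue, rel=1e-10)
        assert np.sign(z_b) == np.sign(beta1)

    def test_identical_groups_null(self):
        y = np.array([2.0, 3.0, 2.0, 3.0])
        presence = np.array([1, 1, 0, 0], dtype=bool)
        beta1, _, p_b = binary_test(y, presence)
        assert beta1 == pytest.approx(0.0)
        assert p_b == pytest.approx(1.0)

    def test_constant_presence_is_na(self):
        y = np.arange(6.0)
        beta1, z_b, p_b = binary_test(y, np.ones(6, dtype=bool))
        assert np.isnan(beta1) and np.isnan(z_b) and np.isnan(p_b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            binary_test(np.arange(4.0), np.ones(3, dtype=bool))


class TestQuantitativeTest:
    def test_exact_linear_fit(self, rng):
        rel = np.concatenate([rng.uniform(1e-4, 1e-2, 10), np.zeros(5)])
        pres = rel > 0
        q = np.zeros(15)
        q[pres] = (np.log(rel[pres]) - np.log(rel[pres]).mean()) / np.log(rel[pres]).std(ddof=1)
        y = 2.0 + 1.7 * q
        beta2, z_q, p_q = quantitative_test(y, rel)
        assert beta2 == pytest.approx(1.7, abs=1e-9)
        assert p_q < 1e-6 and abs(z_q) > 4

    def test_constant_y_null(self, rng):
        rel = rng.uniform(1e-4, 1e-2, 12)
        beta2, _, p_q = quantitative_test(np.full(12, 5.0), rel)
        assert beta2 == pytest.approx(0.0)
        assert p_q == pytest.approx(1.0)

    def test_below_min_present_is_na(self, rng):
        rel = np.array([0.1, 0.2, 0.3, 0.0, 0.0, 0.0])
        beta2, z_q, p_q = quantitative_test(rng.normal(size=6), rel, min_present=5)
        assert np.isnan(beta2) and np.isnan(p_q)

    def test_zero_variance_abundance_is_na(self):
        rel = np.full(10, 0.05)
        beta2, _, p_q = quantitative_test(np.arange(10.0), rel)
        assert np.isnan(beta2) and np.isnan(p_q)


class TestMetaCombine:
    def test_null_stays_null(self):
        z, p = meta_combine(0.0, 100, 0.0, 25)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_weighted_z_arithmetic(self):
        z, p = meta_combine(2.0, 100, 0.0, 25)
        assert z == pytest.approx(20.0 / np.sqrt(125.0))
        assert p == pytest.approx(2 * sps.norm.sf(z))

    def test_na_part_falls_back(self):
        z, _ = meta_combine(1.3, 50, float("nan"), 10)
        assert z == pytest.approx(1.3)
        z, _ = meta_combine(float("nan"), 50, -0.7, 10)
        assert z == pytest.approx(-0.7)

    def test_both_na(self):
        z, p = meta_combine(float("nan"), 50, float("nan"), 10)
        assert np.isnan(z) and np.isnan(p)


class TestTwoPartSingle:
    def test_ubiquitous_otu_reduces_to_quantitative(self, rng):
        rel = rng.uniform(1e-4, 1e-2, 30)
        y = rng.normal(size=30)
        rec = two_part_single(y, rel)
        assert np.isnan(rec["p_b"])
        assert rec["z_meta"] == pytest.approx(rec["z_q"])
        assert rec["p_final"] == pytest.approx(min(rec["p_q"], rec["p_meta"]))

    def test_constant_y_gives_p_one(self, rng):
        rel = np.concatenate([rng.uniform(1e-4, 1e-2, 20), np.zeros(10)])
        rec = two_part_single(np.full(30, 3.3), rng.permutation(rel))
        assert rec["p_final"] == pytest.approx(1.0)

    def test_strong_presence_effect_detected(self, rng):
        n = 100
        pres = rng.random(n) < 0.5
        rel = np.where(pres, rng.uniform(1e-4, 1e-2, n), 0.0)
        y = rng.normal(size=n)
        y = y + 2.0 * y.std() * pres
        rec = two_part_single(y, rel)
        assert rec["p_final"] < 1e-4
        assert rec["z_report"] > 0  # sign matches the planted direction


class TestBhFdr:
    def test_hand_computed_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_single_p(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p).all()


def _null_prep(rng, m, n, prevalence=0.6, min_present=5):
    pres = rng.random((m, n)) < prevalence
    rel = np.where(pres, rng.lognormal(-6, 1, (m, n)), 0.0)
    return prepare_two_part(rel, pres, min_present), rel


class TestPermutation:
    def test_floor_is_one_over_nperm_plus_one(self, rng):
        n = 40
        pres = np.zeros(n, dtype=bool)
        pres[:20] = True
        rel = np.where(pres, 1e-3, 0.0)[None, :]
        y = rng.normal(size=n) + 50.0 * pres  # overwhelming effect
        prep = prepare_two_part(rel, pres[None, :], 5)
        obs = two_part_stats(y, prep)
        p_perm = permutation_correct(y, prep, obs.p_final, 200,
                                     np.random.default_rng(0))
        assert p_perm[0] == pytest.approx(1.0 / 201.0)

    def test_constant_y_gives_p_one(self, rng):
        prep, _ = _null_prep(rng, 5, 30)
        y = np.full(30, 2.0)
        obs = two_part_stats(y, prep)
        p_perm = permutation_correct(y, prep, obs.p_final, 50,
                                     np.random.default_rng(1))
        assert np.allclose(p_perm, 1.0)

    def test_invariant_to_sample_relabeling(self, rng):
        """Jointly permuting samples of (y, table) leaves p_perm unchanged."""
        m, n = 8, 40
        prep, rel = _null_prep(rng, m, n)
        y = rng.normal(size=n)
        perm = rng.permutation(n)
        prep2 = prepare_two_part(rel[:, perm], rel[:, perm] > 0, 5)
        obs1 = two_part_stats(y, prep)
        obs2 = two_part_stats(y[perm], prep2)
        assert np.allclose(obs1.p_final, obs2.p_final, equal_nan=True)
        # observed statistics are exactly invariant; the Monte-Carlo p only up
        # to permutation-sampling noise (3 binomial SEs at n_perm = 400)
        pp1 = permutation_correct(y, prep, obs1.p_final, 400, np.random.default_rng(2))
        pp2 = permutation_correct(y[perm], prep2, obs2.p_final, 400,
                                  np.random.default_rng(3))
        se = 3 * np.sqrt(pp1 * (1 - pp1) / 400)
        assert (np.abs(pp1 - pp2) <= se + 2.0 / 400).all()

    def test_min_p_anticonservative_but_p_perm_calibrated(self, rng):
        """The analytic min-p under the null is stochastically smaller than
        uniform (the reason the permutation step exists); the permutation p
        is approximately uniform."""
        m, n = 400, 60
        prep, _ = _null_prep(rng, m, n)
        y = rng.normal(size=n)
        obs = two_part_stats(y, prep)
        frac_small = np.mean(obs.p_final[~np.isnan(obs.p_final)] <= 0.05)
        assert frac_small > 0.075  # > nominal 0.05: anticonservative
        p_perm = permutation_correct(y, prep, obs.p_final, 150,
                                     np.random.default_rng(3))
        p_perm = p_perm[~np.isnan(p_perm)]
        for dec in np.arange(0.1, 1.0, 0.1):
            assert abs(np.mean(p_perm <= dec) - dec) < 0.09


class TestRunTwoPart:
    def _cohort(self, rng, m=40, n=60):
        pres = rng.random((m, n)) < rng.uniform(0.2, 0.9, m)[:, None]
        raw = np.where(pres, rng.lognormal(0, 1, (m, n)), 0.0)
        raw[:, raw.sum(axis=0) == 0] = 1  # avoid empty samples (rare)
        counts = np.floor(raw / raw.sum(axis=0) * 10_000).astype(int) + pres
        return CountTable([f"o{i}" for i in range(m)],
                          [f"s{j}" for j in range(n)], counts)

    def test_deterministic_given_seed(self, rng):
        table = self._cohort(rng)
        y = np.random.default_rng(5).normal(size=table.n_samples)
        cfg = TwoPartConfig(n_perm=50, seed=11)
        a = run_two_part(table, y, cfg)
        b = run_two_part(table, y, cfg)
        assert a.equals(b)

    def test_row_accounting_and_invariants(self, rng):
        table = self._cohort(rng)
        y = rng.normal(size=table.n_samples)
        res = run_two_part(table, y, TwoPartConfig(n_perm=50, seed=1))
        pres = table.presence().sum(axis=1)
        n = table.n_samples
        has_valid_part = ((pres >= 2) & (pres <= n - 2)) | (pres >= 5)
        assert len(res) == int(has_valid_part.sum())
        assert ((res["p_perm"] > 0) & (res["p_perm"] <= 1)).all()
        assert (res["p_perm"] >= 1.0 / 51.0 - 1e-12).all()
        assert (res["q_fdr"] >= res["p_perm"] - 1e-12).all()
        finite = res.dropna(subset=["z_report"])
        assert ((finite["p_final"] > 0) & (finite["p_final"] <= 1)).all()

    def test_too_few_samples_rejected(self):
        table = CountTable(["o1"], [f"s{j}" for j in range(5)],
                           np.ones((1, 5), dtype=int))
        with pytest.raises(ValueError, match="at least 10 samples"):
            run_two_part(table, np.zeros(5), TwoPartConfig(n_perm=5))

    def test_effect_sign_propagates_to_z_report(self, rng):
        n = 80
        pres = rng.random(n) < 0.5
        rel = np.where(pres, rng.uniform(1e-4, 1e-2, n), 0.0)
        y = rng.normal(size=n) - 3.0 * pres  # strong negative presence effect
        rec = two_part_single(y, rel)
        assert rec["z_report"] < 0
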