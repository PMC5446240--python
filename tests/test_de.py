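"""Differential-induction engine: filtering, TMM, log-CPM, the
genotype-means model, variance moderation, the threshold fold-change
test, and globally pooled BH — each checked against an independent
oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phocycle import de, syndata
from phocycle.de import (
    CONTRAST_WITH_COFACTOR,
    CONTRAST_WITHOUT_COFACTOR,
    CountMatrix,
    DEFit,
    G_COFACTOR_ONLY,
    G_FULL,
    G_NULL,
    G_TF_ONLY,
    GENOTYPES,
)

from conftest import make_count_matrix


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        counts = np.vstack([np.zeros(8), np.full(8, 100)]).astype(int)
        cm = make_count_matrix(counts)
        out = de.filter_low_expression(cm)
        assert list(out.counts.index) == ["g1"]

    def test_high_cpm_gene_retained(self):
        counts = np.full((3, 8), 5000)
        cm = make_count_matrix(counts)
        out = de.filter_low_expression(cm)
        assert out.counts.shape[0] == 3

    def test_matches_brute_force_rule(self, rng):
        counts = rng.integers(0, 40, size=(20, 8))
        counts[0] += 10_000  # make library sizes large enough for CPM<1 to occur
        cm = make_count_matrix(counts)
        out = de.filter_low_expression(cm, min_cpm=1.0, min_low_samples=3)
        lib = counts.sum(axis=0)
        expected = [
            f"g{i}"
            for i in range(20)
            if sum(counts[i, j] / lib[j] * 1e6 < 1.0 for j in range(8)) < 3
        ]
        assert list(out.counts.index) == expected

    def test_empty_result_raises(self):
        # each gene dominates exactly one sample, so every gene has zero
        # CPM in the seven others and the filter removes them all
        counts = np.eye(8, dtype=int) * 10_000_000
        cm = make_count_matrix(counts)
        with pytest.raises(de.EmptyResultError):
            de.filter_low_expression(cm)


def tmm_oracle_two_samples(obs, ref, trim_m=0.3, trim_a=0.05):
    """Step-by-step spreadsheet-style computation of the trimmed
    weighted mean of per-gene log ratios, independent of the package."""
    n_obs, n_ref = sum(obs), sum(ref)
    rows = []
    for o, r in zip(obs, ref):
        if o == 0 or r == 0:
            continue
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        rows.append((m, a, w))
    n = len(rows)
    lo = int(np.floor(n * trim_m)) + 1
    hi = n + 1 - lo
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    m_rank = stats.rankdata([r[0] for r in rows])
    a_rank = stats.rankdata([r[1] for r in rows])
    kept = [
        rows[i]
        for i in range(n)
        if lo <= m_rank[i] <= hi and lo_a <= a_rank[i] <= hi_a
    ]
    f = sum(m * w for m, _, w in kept) / sum(w for _, _, w in kept)
    return 2.0 ** f


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        counts = np.tile(np.array([[10, 50, 100, 400, 1000, 40, 7, 3]]).T, (1, 8))
        nf = de.tmm_factors(make_count_matrix(counts))
        assert np.allclose(nf.factors, 1.0)

    def test_depth_change_without_composition_change(self):
        base = np.array([10, 50, 100, 400, 1000, 40])
        counts = np.column_stack([base] + [2 * base] + [base] * 6)
        nf = de.tmm_factors(make_count_matrix(counts))
        assert np.allclose(nf.factors, 1.0)

    def test_crafted_six_gene_case_matches_hand_computation(self):
        a = [100, 200, 300, 400, 500, 1000]
        b = [100, 200, 300, 400, 500, 10000]
        counts = np.column_stack([a, b, a, a, a, a, a, a])
        cm = make_count_matrix(counts)
        nf = de.tmm_factors(cm, ref_sample="s0")
        f_b = tmm_oracle_two_samples(b, a)
        expected = np.array([1.0] * 8, dtype=float)
        expected[1] = f_b
        expected /= np.exp(np.mean(np.log(expected)))
        for i in range(8):
            assert nf.factors[f"s{i}"] == pytest.approx(expected[i], abs=1e-4)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(1, 2000, size=(50, 8))
        nf = de.tmm_factors(make_count_matrix(counts))
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_order_equivariance(self, rng):
        counts = rng.integers(1, 2000, size=(60, 8))
        cm = make_count_matrix(counts)
        nf = de.tmm_factors(cm, ref_sample="s3")
        perm = ["s5", "s2", "s7", "s0", "s1", "s3", "s4", "s6"]
        cm_perm = CountMatrix(cm.counts[perm], cm.sheet)
        nf_perm = de.tmm_factors(cm_perm, ref_sample="s3")
        for s in perm:
            assert nf_perm.factors[s] == pytest.approx(nf.factors[s], abs=1e-12)

    def test_zero_overlap_sample_warns_factor_one(self):
        counts = np.zeros((4, 8), dtype=int)
        counts[:2, 0] = [100, 200]          # s0 expresses genes 0-1 only
        counts[2:, 1:] = 50                 # everyone else genes 2-3 only
        cm = make_count_matrix(counts)
        with pytest.warns(UserWarning, match="no genes shared"):
            de.tmm_factors(cm, ref_sample="s1")


class TestLogCPM:
    def test_zero_count_closed_form(self):
        counts = np.zeros((1, 8), dtype=int)
        cm = make_count_matrix(counts)
        nf = de.NormFactors(
            lib_sizes=pd.Series(1e6, index=cm.counts.columns),
            factors=pd.Series(1.0, index=cm.counts.columns),
            ref_sample="s0",
        )
        lc = de.log_cpm(cm, nf)
        assert lc.iloc[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-3)
        assert lc.iloc[0, 0] == pytest.approx(-1.0, abs=1e-2)

    def test_doubling_large_count_adds_one(self):
        counts = np.array([[10_000] * 8, [20_000] * 8])
        cm = make_count_matrix(counts)
        nf = de.tmm_factors(cm)
        lc = de.log_cpm(cm, nf)
        assert lc.iloc[1, 0] - lc.iloc[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_formula_oracle_on_random_cells(self, rng):
        counts = rng.integers(0, 5000, size=(30, 8))
        cm = make_count_matrix(counts)
        nf = de.tmm_factors(cm)
        lc = de.log_cpm(cm, nf, pseudocount=0.5)
        for _ in range(100):
            i, j = rng.integers(30), rng.integers(8)
            s = cm.counts.columns[j]
            eff = nf.lib_sizes[s] * nf.factors[s]
            expected = np.log2((counts[i, j] + 0.5) / (eff + 1) * 1e6)
            assert lc.iloc[i, j] == pytest.approx(expected, abs=1e-12)


class TestGenotypeMeans:
    def test_two_identical_replicates(self):
        lc = pd.DataFrame(
            [[5.0, 5.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0]],
            index=["g0"], columns=[f"s{i}" for i in range(8)],
        )
        cm = make_count_matrix(np.ones((1, 8), dtype=int))
        fit = de.fit_genotype_means(lc, cm.sheet)
        assert fit.beta.loc["g0", GENOTYPES[0]] == 5.0
        assert fit.s2["g0"] == 0.0

    def test_mean_and_variance_arithmetic(self):
        # replicates (4, 6) in one genotype: beta = 5, RSS contribution = 2
        lc = pd.DataFrame(
            [[4.0, 6.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]],
            index=["g0"], columns=[f"s{i}" for i in range(8)],
        )
        cm = make_count_matrix(np.ones((1, 8), dtype=int))
        fit = de.fit_genotype_means(lc, cm.sheet)
        assert fit.beta.loc["g0", GENOTYPES[0]] == 5.0
        assert fit.s2["g0"] == pytest.approx(2.0 / fit.df_resid)
        assert fit.df_resid == 4

    def test_matches_ols_with_indicator_design(self, rng):
        lc = pd.DataFrame(
            rng.normal(5, 2, size=(15, 8)), columns=[f"s{i}" for i in range(8)]
        )
        cm = make_count_matrix(np.ones((15, 8), dtype=int))
        fit = de.fit_genotype_means(lc, cm.sheet)
        design = np.zeros((8, 4))
        for j, g in enumerate(cm.sheet["genotype"]):
            design[j, GENOTYPES.index(g)] = 1.0
        for i in range(15):
            y = lc.iloc[i].to_numpy()
            beta, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
            np.testing.assert_allclose(fit.beta.iloc[i].to_numpy(), beta, atol=1e-10)
            assert fit.s2.iloc[i] == pytest.approx(float(rss[0]) / 4, abs=1e-10)

    def test_contrast_linearity(self, rng):
        lc = pd.DataFrame(
            rng.normal(5, 2, size=(10, 8)), columns=[f"s{i}" for i in range(8)]
        )
        cm = make_count_matrix(np.ones((10, 8), dtype=int))
        fit = de.fit_genotype_means(lc, cm.sheet)
        ab = fit.beta[G_FULL] - fit.beta[G_TF_ONLY]
        bc = fit.beta[G_TF_ONLY] - fit.beta[G_NULL]
        ac = fit.beta[G_FULL] - fit.beta[G_NULL]
        np.testing.assert_allclose(ab + bc, ac, atol=1e-12)


def _fit_with_s2(s2: np.ndarray, d: int) -> DEFit:
    idx = [f"g{i}" for i in range(s2.size)]
    return DEFit(
        beta=pd.DataFrame(0.0, index=idx, columns=list(GENOTYPES)),
        s2=pd.Series(s2, index=idx),
        df_resid=d,
        n_per_genotype=pd.Series(2, index=list(GENOTYPES)),
    )


class TestModeration:
    def test_equal_variances_give_infinite_prior_df(self):
        fit = _fit_with_s2(np.full(100, 0.25), d=4)
        out = de.moderate_variances(fit)
        assert np.isinf(out.d0)
        assert np.allclose(out.s2_tilde, out.s0_2)

    def test_posterior_is_df_weighted_average(self, rng):
        fit = _fit_with_s2(rng.chisquare(4, 200) / 4 * 0.09, d=4)
        out = de.moderate_variances(fit)
        expected = (out.d0 * out.s0_2 + 4 * out.s2) / (out.d0 + 4)
        np.testing.assert_allclose(out.s2_tilde, expected, atol=1e-12)

    def test_prior_recovery_from_simulated_variances(self):
        # known scaled-F world: sigma^2 ~ s0^2 * d0 / chisq(d0), s^2 ~ sigma^2 chisq(d)/d
        rng = np.random.default_rng(7)
        d0, s0_2, d, n = 4.0, 0.04, 4, 5000
        sigma2 = s0_2 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        out = de.moderate_variances(_fit_with_s2(s2, d))
        assert out.d0 == pytest.approx(d0, rel=0.30)
        assert out.s0_2 == pytest.approx(s0_2, rel=0.15)


class TestTreat:
    @pytest.fixture()
    def moderated_fit(self, rng):
        lc = pd.DataFrame(
            rng.normal(5, 1, size=(100, 8)), columns=[f"s{i}" for i in range(8)]
        )
        cm = make_count_matrix(np.ones((100, 8), dtype=int))
        fit = de.fit_genotype_means(lc, cm.sheet)
        return de.moderate_variances(fit)

    def test_reduces_to_moderated_t_at_zero_threshold(self, moderated_fit):
        res = de.treat_test(moderated_fit, CONTRAST_WITH_COFACTOR, lfc=0.0)
        t = res["logFC"].abs() / res["se"]
        expected = 2 * stats.t.sf(t, moderated_fit.df_total)
        np.testing.assert_allclose(res["p"], np.minimum(expected, 1.0), atol=1e-12)

    def test_boundary_fold_change_p_above_half(self, moderated_fit):
        fit = moderated_fit
        fit.beta[G_FULL] = fit.beta[G_COFACTOR_ONLY] + 1.0  # |logFC| == lfc
        res = de.treat_test(fit, CONTRAST_WITH_COFACTOR, lfc=1.0)
        assert ((res["p"] > 0.5) & (res["p"] <= 1.0)).all()

    def test_zero_se_edge_cases(self):
        fit = _fit_with_s2(np.zeros(2), d=4)
        fit.d0, fit.s0_2 = 0.0, 0.0
        fit.s2_tilde = pd.Series([0.0, 0.0], index=fit.s2.index)
        fit.beta.loc["g0", G_FULL] = 3.0   # |logFC| > lfc
        fit.beta.loc["g1", G_FULL] = 0.5   # |logFC| < lfc
        res = de.treat_test(fit, CONTRAST_WITH_COFACTOR, lfc=1.0)
        assert res.loc["g0", "p"] == 0.0
        assert res.loc["g1", "p"] == 1.0


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: q_(i) = min over j>=i of p_(j) * n / j."""
    n = p.size
    order = np.argsort(p)
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestGlobalBH:
    def _as_tests(self, p: np.ndarray) -> dict[str, pd.DataFrame]:
        half = p.size // 2
        mk = lambda v: pd.DataFrame(  # noqa: E731
            {"logFC": np.full(v.size, 2.0), "se": 0.1, "p": v}
        )
        return {"a": mk(p[:half]), "b": mk(p[half:])}

    def test_single_p_unchanged(self):
        out = de.bh_adjust_global({"a": pd.DataFrame({"logFC": [2.0], "p": [0.01]})})
        assert out["a"]["q"].iloc[0] == pytest.approx(0.01)

    def test_four_value_arithmetic(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        out = de.bh_adjust_global({"a": pd.DataFrame({"logFC": [2.0] * 4, "p": p})})
        np.testing.assert_allclose(out["a"]["q"], 0.04)

    def test_matches_textbook_oracle_and_pools_contrasts(self, rng):
        p = rng.uniform(size=200)
        out = de.bh_adjust_global(self._as_tests(p))
        got = np.concatenate([out["a"]["q"], out["b"]["q"]])
        np.testing.assert_allclose(got, bh_oracle(p), atol=1e-12)
        # pooled adjustment implies one raw-p cutoff across contrasts
        rejected = p[got < 0.05]
        accepted = p[got >= 0.05]
        if rejected.size and accepted.size:
            assert rejected.max() < accepted.min()

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=101)
        out = de.bh_adjust_global({"a": pd.DataFrame({"logFC": [2.0] * 101, "p": p})})
        df = out["a"].sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-15).all()


class TestPipelineRecovery:
    def test_sensitivity_and_fdr_on_planted_truth(self):
        """2 replicates/genotype, dispersion 0.05, 2,000 genes with 10%
        induced: sensitivity >= 0.9 for planted fold >= 4 and empirical
        FDR <= 0.10 among induced flags, averaged over seeds."""
        sens, fdr_vals = [], []
        for seed in range(20):
            truth = syndata.make_expression_truth(
                [f"g{i}" for i in range(2000)], frac_induced=0.10, seed=seed
            )
            cm = syndata.simulate_counts(truth, n_replicates=2, seed=seed + 10_000)
            fit, calls = de.run_de(cm)
            tab = calls["with_cofactor"]
            truth_sub = truth.loc[tab.index]
            planted_fc = truth_sub["X_Pho4"] + truth_sub["CO"]
            strong = planted_fc >= 2.0  # fold >= 4
            called = tab["induced"]
            sens.append((called & strong).sum() / strong.sum())
            if called.sum():
                fdr_vals.append((called & (planted_fc == 0)).sum() / called.sum())
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr_vals) <= 0.10


class TestRunDE:
    def test_induced_implies_logfc_above_threshold(self):
        truth = syndata.make_expression_truth(
            [f"g{i}" for i in range(500)], frac_induced=0.2, seed=3
        )
        cm = syndata.simulate_counts(truth, seed=3)
        _, calls = de.run_de(cm, lfc=1.0)
        for tab in calls.values():
            assert (tab.loc[tab["induced"], "logFC"] > 1.0).all()

    def test_without_cofactor_contrast_ignores_co_component(self):
        truth = syndata.make_expression_truth(
            [f"g{i}" for i in range(400)], frac_induced=0.0, seed=4
        )
        truth.loc["g0", "CO"] = 4.0  # class II: induction needs the cofactor
        cm = syndata.simulate_counts(truth, seed=4)
        _, calls = de.run_de(cm)
        assert bool(calls["with_cofactor"].loc["g0", "induced"])
        assert not bool(calls["without_cofactor"].loc["g0", "induced"])
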