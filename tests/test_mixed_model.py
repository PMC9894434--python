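"""Mixed-model stage: transforms, contrasts, REML, Wald tests, Holm."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from veracue import mixed_model as mm


def balanced_meta(n_subjects):
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"s{i:03d}" for i in range(n_subjects)], 4),
            "veracity": ["truth", "lie", "truth", "lie"] * n_subjects,
            "modality": ["written", "written", "transcribed", "transcribed"]
            * n_subjects,
        }
    )


class TestTransform:
    def test_zero_maps_to_zero_both_paths(self):
        assert mm.normalize_and_transform([0.0], [10], normalize=True)[0] == 0.0
        assert mm.normalize_and_transform([0.0], normalize=False)[0] == 0.0

    def test_rate_transform(self):
        out = mm.normalize_and_transform([6.0], [6], normalize=True)
        assert out[0] == pytest.approx(math.log(2.0))

    def test_log_inverse_identity(self):
        out = mm.normalize_and_transform([math.e - 1.0], normalize=False)
        assert out[0] == pytest.approx(1.0)

    def test_missing_propagates(self):
        out = mm.normalize_and_transform([math.nan, 1.0], [5, 5], normalize=True)
        assert math.isnan(out[0]) and not math.isnan(out[1])

    def test_zero_tokens_rejected(self):
        with pytest.raises(ValueError, match="n_tokens"):
            mm.normalize_and_transform([1.0], [0], normalize=True)


class TestDesign:
    def test_contrast_rows(self):
        meta = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "veracity": ["truth", "lie"],
                "modality": ["written", "transcribed"],
            }
        )
        d = mm.build_design(meta)
        assert d.X[0].tolist() == [1.0, -0.5, -0.5, 0.25]
        assert d.X[1].tolist() == [1.0, 0.5, 0.5, 0.25]

    def test_balanced_contrasts_sum_to_zero(self):
        d = mm.build_design(balanced_meta(7))
        assert d.X[:, 1].sum() == 0.0
        assert d.X[:, 2].sum() == 0.0
        np.testing.assert_allclose(d.X[:, 3], d.X[:, 1] * d.X[:, 2])

    def test_unknown_level_rejected(self):
        meta = pd.DataFrame(
            {"subject_id": ["a"], "veracity": ["maybe"], "modality": ["written"]}
        )
        with pytest.raises(mm.DesignError):
            mm.build_design(meta)


class TestReml:
    def test_zero_subject_variance_matches_ols(self):
        rng = np.random.default_rng(42)
        d = mm.build_design(balanced_meta(50))
        y = d.X @ np.array([1.0, 0.3, -0.2, 0.1]) + rng.normal(0, 0.5, d.X.shape[0])
        fit = mm.fit_lmm_reml(y, d)
        beta_ols = np.linalg.lstsq(d.X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_constant_response_degenerate(self):
        d = mm.build_design(balanced_meta(5))
        fit = mm.fit_lmm_reml(np.full(20, 2.5), d)
        np.testing.assert_allclose(fit.beta, [2.5, 0, 0, 0], atol=1e-10)
        assert fit.sigma2_subject == 0.0 and fit.sigma2_resid == 0.0
        assert np.isnan(fit.p).all()

    def test_matches_independent_reml_implementation(self):
        """Cross-check against statsmodels MixedLM (independent REML)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        n_subj = 60
        d = mm.build_design(balanced_meta(n_subj))
        u = rng.normal(0, 0.6, n_subj)
        y = d.X @ np.array([0.5, 0.2, 0.1, 0.0]) + np.repeat(u, 4) + rng.normal(
            0, 0.4, 4 * n_subj
        )
        fit = mm.fit_lmm_reml(y, d)
        ref = sm.MixedLM(y, d.X, groups=np.repeat(np.arange(n_subj), 4)).fit(reml=True)
        np.testing.assert_allclose(fit.beta, ref.fe_params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse_fe, atol=1e-5)
        assert fit.sigma2_subject == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4
        )
        assert fit.sigma2_resid == pytest.approx(ref.scale, abs=1e-4)

    def test_optimizer_certificate_on_grid(self):
        """The REML objective at the returned ratio beats a 50-point grid."""
        rng = np.random.default_rng(3)
        n_subj = 40
        d = mm.build_design(balanced_meta(n_subj))
        y = (
            d.X @ np.array([0.2, 0.1, 0.0, 0.0])
            + np.repeat(rng.normal(0, 0.7, n_subj), 4)
            + rng.normal(0, 0.5, 4 * n_subj)
        )
        fit = mm.fit_lmm_reml(y, d)
        Xs, ys, starts, counts = mm._group_stats(d.X, y, d.groups)
        best = mm._neg2_reml(fit.lambda_ratio, Xs, ys, starts, counts)
        grid = np.concatenate([[0.0], np.geomspace(1e-4, mm.LAMBDA_MAX, 49)])
        for lam in grid:
            assert best <= mm._neg2_reml(lam, Xs, ys, starts, counts) + 1e-8

    def test_parameter_recovery_seeded(self):
        """Mean estimate of a planted veracity effect is close to truth."""
        rng = np.random.default_rng(2024)
        n_subj = 100
        d = mm.build_design(balanced_meta(n_subj))
        est = []
        for _ in range(50):
            u = rng.normal(0, 0.5, n_subj)
            y = (
                d.X @ np.array([1.0, 0.3, 0.0, 0.0])
                + np.repeat(u, 4)
                + rng.normal(0, 0.5, 4 * n_subj)
            )
            est.append(mm.fit_lmm_reml(y, d).beta[1])
        assert np.mean(est) == pytest.approx(0.3, abs=0.05)

    def test_singular_design_rejected(self):
        meta = balanced_meta(5).copy()
        meta["modality"] = "written"  # drops one factor level
        with pytest.raises(mm.DesignError):
            mm.fit_lmm_reml(np.zeros(20), mm.build_design(meta))


class TestWald:
    def _fit(self, beta, se):
        return mm.MixedModelFit(
            beta=np.asarray(beta, dtype=float),
            se=np.asarray(se, dtype=float),
            sigma2_subject=0.1,
            sigma2_resid=0.1,
            lambda_ratio=1.0,
            loglik_reml=0.0,
            converged=True,
            n_obs=100,
            n_groups=25,
        )

    def test_zero_effect_gives_p_one(self):
        p = mm.wald_pvalues(self._fit([0.0], [1.0]))
        assert p[0] == pytest.approx(1.0)

    def test_quantile_1959964_gives_p_05(self):
        p = mm.wald_pvalues(self._fit([1.959964], [1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_sign_symmetry(self):
        p_pos = mm.wald_pvalues(self._fit([0.7], [0.3]))
        p_neg = mm.wald_pvalues(self._fit([-0.7], [0.3]))
        assert p_pos[0] == p_neg[0]

    def test_zero_se_flagged_nan(self):
        p = mm.wald_pvalues(self._fit([0.5], [0.0]))
        assert np.isnan(p[0])


def brute_force_holm(p):
    """Independent oracle: literal step-down definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        prev = max(prev, val)
        adj[idx] = prev
    return adj


class TestHolm:
    def test_three_value_worked_case(self):
        np.testing.assert_allclose(
            mm.holm_p([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert mm.holm_p([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(mm.holm_p([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(mm.holm_p(p), brute_force_holm(p), atol=1e-12)

    def test_matches_statsmodels(self):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest"
        ).multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=30)
        np.testing.assert_allclose(mm.holm_p(p), multipletests(p, method="holm")[1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(mm.holm_p(p)[perm], mm.holm_p(p[perm]))

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=20)
        adj = mm.holm_p(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_holm_adjust_records(self):
        res = mm.holm_adjust([0.001, 0.5], variables=["a", "b"])
        assert res[0].significant and not res[1].significant
        assert res[0].p_adj == pytest.approx(0.002)


class TestAnalyzeAll:
    def test_deterministic_rerun(self, small_table):
        a = mm.analyze_all(small_table)
        b = mm.analyze_all(small_table)
        pd.testing.assert_frame_equal(a, b)

    def test_effects_reported_per_variable(self, small_table):
        res = mm.analyze_all(small_table)
        assert set(res["effect"]) == {"intercept", "veracity", "modality", "interaction"}
        counts = res.groupby("variable").size()
        assert (counts == 4).all()
        tested = res[res["effect"] != "intercept"]
        assert tested["p_holm"].notna().all()
        assert (tested["p_holm"] >= tested["p_raw"] - 1e-15).all()

    def test_planted_positive_sentiment_lie_effect(self):
        """A planted lie > truth positive-sentiment shift is detected with
        the right sign and survives Holm at a realistic sample size."""
        from veracue import lexicon_features as lf
        from veracue import synthetic_data as sd

        em = sd._default_emissions()
        em["pos_sentiment"] = sd.FamilyEffect(0.04, veracity=0.5)
        effects = sd.EffectSpec(emissions=em)
        corpus, lexicons, _ = sd.generate_corpus(150, effects, seed=21)
        table = lf.extract_table(corpus, lexicons)
        res = mm.analyze_all(table)
        row = res[(res.variable == "pos_sentiment") & (res.effect == "veracity")]
        assert row["b"].iloc[0] > 0
        assert row["p_holm"].iloc[0] < 0.05
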