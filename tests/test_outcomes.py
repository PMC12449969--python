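"""Regression overlays: parameter recovery, Fine-Gray/Cox reduction,
Moran's I calibration, elastic-net explainability, model comparison,
multiple testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenotree.outcomes import (
    ModelFitError,
    ModelResult,
    adjust_pvalues,
    compare_prognostic_models,
    explain_phenogroups,
    finegray_expand,
    fit_adjusted_model,
    morans_i,
    risk_surface,
)
from phenotree.synthetic import SyntheticOutcomeSpec, generate_cohort
from phenotree.tree import assign_branches, compute_pseudotime, fit_ddrtree


def _ph_data(seed, n=800, beta=0.7, competing=False, cens_scale=100.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t_event = rng.exponential(1.0 / (0.01 * np.exp(beta * x)))
    t_cens = rng.exponential(cens_scale, n)
    t = np.minimum(t_event, t_cens)
    e = (t_event <= t_cens).astype(int)
    if competing:
        t_death = rng.exponential(150.0, n)
        e = np.where(t_death < t, 2, e)
        t = np.minimum(t, t_death)
    return pd.DataFrame({"x": x, "time_to_event": t, "event_indicator": e})


class TestAdjustedModels:
    def test_logistic_or_recovery(self):
        """Planted OR = 2.0 recovered within +-0.3 (20-seed average)."""
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=5000)
            p = 1 / (1 + np.exp(-(-0.5 + np.log(2.0) * x)))
            y = (rng.random(5000) < p).astype(int)
            res = fit_adjusted_model(
                pd.DataFrame({"x": x, "y": y}), "y", ["x"],
                kind="logistic", reference_phenogroup=None)
            ests.append(res.term("x")["exp_estimate"])
        assert np.mean(ests) == pytest.approx(2.0, abs=0.3)

    def test_null_covariate_ci_coverage(self):
        """A covariate independent of the outcome: 95% CI covers OR = 1
        in >= 90% of 50 simulations."""
        cover = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=500)
            y = (rng.random(500) < 0.3).astype(int)
            res = fit_adjusted_model(
                pd.DataFrame({"x": x, "y": y}), "y", ["x"],
                kind="logistic", reference_phenogroup=None)
            t = res.term("x")
            cover += t["ci_low"] <= 1.0 <= t["ci_high"]
        assert cover >= 45

    def test_linear_kind(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.5, 400)
        res = fit_adjusted_model(pd.DataFrame({"x": x, "y": y}), "y",
                                 ["x"], kind="linear",
                                 reference_phenogroup=None)
        assert res.term("x")["estimate"] == pytest.approx(1.5, abs=0.1)

    def test_cox_loghr_recovery_bias_below_5pct(self):
        """Cox on exponential PH simulations: bias < 5% of the true
        log-HR at n = 5000 over 20 seeds."""
        ests = []
        for seed in range(20):
            df = _ph_data(seed, n=5000, beta=0.7)
            res = fit_adjusted_model(df, "ev", ["x"], kind="cox",
                                     reference_phenogroup=None)
            ests.append(res.term("x")["estimate"])
        assert abs(np.mean(ests) - 0.7) < 0.05 * 0.7

    def test_finegray_equals_cox_without_competing_events(self):
        df = _ph_data(3, n=600)
        rc = fit_adjusted_model(df, "ev", ["x"], kind="cox",
                                reference_phenogroup=None)
        rf = fit_adjusted_model(df, "ev", ["x"], kind="fine_gray",
                                reference_phenogroup=None)
        assert abs(rc.term("x")["estimate"]
                   - rf.term("x")["estimate"]) < 1e-6

    def test_finegray_detects_planted_effect_with_competing_risk(self):
        df = _ph_data(4, n=2000, beta=0.7, competing=True)
        rf = fit_adjusted_model(df, "ev", ["x"], kind="fine_gray",
                                reference_phenogroup=None)
        t = rf.term("x")
        assert t["estimate"] > 0.3
        assert t["ci_low"] > 1.0  # exponentiated CI excludes 1

    def test_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.astype(int)  # perfectly separated
        with pytest.raises(ModelFitError):
            fit_adjusted_model(pd.DataFrame({"x": x, "y": y}), "y",
                               ["x"], kind="logistic",
                               reference_phenogroup=None)

    def test_singular_design_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "x2": 2 * x,
                           "y": (rng.random(100) < 0.5).astype(int)})
        with pytest.raises(ModelFitError, match="singular"):
            fit_adjusted_model(df, "y", ["x", "x2"], kind="logistic",
                               reference_phenogroup=None)

    def test_row_order_invariance(self):
        df = _ph_data(5, n=400)
        res1 = fit_adjusted_model(df, "ev", ["x"], kind="cox",
                                  reference_phenogroup=None)
        shuffled = df.sample(frac=1.0, random_state=1)
        res2 = fit_adjusted_model(shuffled, "ev", ["x"], kind="cox",
                                  reference_phenogroup=None)
        assert res1.term("x")["estimate"] == pytest.approx(
            res2.term("x")["estimate"], abs=1e-10)

    def test_affine_rescaling_reparameterizes_exactly(self):
        df = _ph_data(6, n=400)
        res1 = fit_adjusted_model(df, "ev", ["x"], kind="cox",
                                  reference_phenogroup=None)
        df2 = df.assign(x=df.x * 10.0)
        res2 = fit_adjusted_model(df2, "ev", ["x"], kind="cox",
                                  reference_phenogroup=None)
        assert res2.term("x")["estimate"] * 10.0 == pytest.approx(
            res1.term("x")["estimate"], rel=1e-6)

    def test_phenogroup_reference_category(self, small_cohort):
        df = small_cohort.copy()
        rng = np.random.default_rng(0)
        df["phenogroup"] = rng.integers(1, 7, len(df))
        df["prevalent_disease"] = df["prevalent_disease"].astype(int)
        res = fit_adjusted_model(df, "prevalent_disease", ["phenogroup"],
                                 ["age", "sex"], kind="logistic",
                                 reference_phenogroup=4)
        terms = res.table["term"].tolist()
        assert "phenogroup=4" not in terms  # reference level absent
        assert sum(t.startswith("phenogroup=") for t in terms) == 5


class TestFinegrayExpansion:
    def test_identity_without_competing_events(self):
        df = _ph_data(0, n=50)
        df["xcopy"] = df["x"]
        out = finegray_expand(df, "time_to_event", "event_indicator",
                              ["x"])
        assert len(out) == 50
        assert (out["_w"] == 1.0).all()

    def test_competing_subjects_extended_with_decreasing_weights(self):
        df = _ph_data(1, n=200, competing=True)
        out = finegray_expand(df, "time_to_event", "event_indicator",
                              ["x"])
        assert len(out) > 200
        ext = out[out["_start"] > 0]
        assert (ext["_w"] <= 1.0).all()
        # weights non-increasing within each extended subject
        for _, grp in ext.groupby("_id"):
            w = grp.sort_values("_start")["_w"].to_numpy()
            assert (np.diff(w) <= 1e-12).all()


class TestRiskSurface:
    @pytest.fixture(scope="class")
    def fitted_tree_cohort(self):
        _, table = generate_cohort(500, class_mix=(1.0, 0.0, 0.0),
                                   seed=13, return_waveforms=False)
        rng = np.random.default_rng(13)
        X = np.column_stack([
            table["severity"] + rng.normal(0, 0.1, len(table)),
            table["qrs_ms"] / 60.0 + rng.normal(0, 0.1, len(table)),
            rng.normal(0, 0.3, len(table)),
        ])
        tree = compute_pseudotime(assign_branches(
            fit_ddrtree(X, n_centroids=40, seed=13)))
        return tree, table

    def test_probabilities_valid_and_monotone_in_horizon(
            self, fitted_tree_cohort):
        tree, table = fitted_tree_cohort
        p1 = risk_surface(tree, table, outcome="event", horizon=500.0)
        p2 = risk_surface(tree, table, outcome="event", horizon=1500.0)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.all((p2 >= 0) & (p2 <= 1))
        assert np.all(p2 >= p1 - 1e-12)

    def test_risk_tracks_generator_severity(self, fitted_tree_cohort):
        tree, table = fitted_tree_cohort
        p = risk_surface(tree, table, outcome="event")
        rho = stats.spearmanr(p, table["severity"]).statistic
        assert rho > 0.5

    def test_death_outcome_uses_cox(self, fitted_tree_cohort):
        tree, table = fitted_tree_cohort
        p = risk_surface(tree, table, outcome="death")
        assert np.all((p >= 0) & (p <= 1))

    def test_null_generator_gives_flat_surface(self):
        spec = SyntheticOutcomeSpec(log_hr_per_severity=0.0)
        _, table = generate_cohort(500, spec=spec, seed=14,
                                   return_waveforms=False)
        rng = np.random.default_rng(14)
        X = rng.normal(size=(500, 3))
        tree = compute_pseudotime(assign_branches(
            fit_ddrtree(X, n_centroids=30, seed=14)))
        p = risk_surface(tree, table, outcome="event")
        assert p.std() < 0.2 * p.mean()


class TestMoransI:
    def test_null_mean_matches_analytic_value(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(120, 2))
        vals = rng.normal(size=120)
        # permutation null mean ~ -1/(N-1) within 2 MC standard errors
        n_perm = 2000
        perms = []
        z = vals - vals.mean()
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=9).fit(coords)
        _, nbrs = nn.kneighbors(coords)
        nbrs = nbrs[:, 1:]
        for _ in range(n_perm):
            zp = rng.permutation(z)
            perms.append(np.sum(zp[:, None] * zp[nbrs] / 8)
                         / np.sum(zp**2))
        mc_se = np.std(perms) / np.sqrt(n_perm)
        assert abs(np.mean(perms) - (-1 / 119)) <= 2 * mc_se

    def test_planted_two_cluster_field(self):
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.normal(0, 1, (100, 2)),
                            rng.normal(10, 1, (100, 2))])
        vals = np.r_[np.zeros(100), np.ones(100)]
        res = morans_i(vals, coords, n_perm=999, seed=0)
        assert res["I"] >= 0.8
        assert res["p_perm"] <= 0.01

    def test_random_values_near_null(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(200, 2))
        res = morans_i(rng.normal(size=200), coords, n_perm=499, seed=1)
        assert abs(res["I"] - res["expected_I"]) < 0.1

    def test_permutation_p_uniform_under_null(self):
        """KS test of permutation p-values across 50 null replicates."""
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(80, 2))
        ps = [
            morans_i(rng.normal(size=80), coords, n_perm=199,
                     seed=int(rng.integers(1 << 30)))["p_perm"]
            for _ in range(50)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(50), np.random.default_rng(0).normal(
                size=(50, 2)))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.arange(5.0), np.zeros((5, 2)))


class TestExplainability:
    def test_planted_single_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 20))
        labels = np.where(X[:, 7] > 0, 1, 2)
        top = explain_phenogroups(X, labels, seed=0)
        assert top[1].iloc[0]["feature"] == 7
        assert top[2].iloc[0]["feature"] == 7

    def test_three_features_reported_per_group(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 15))
        labels = rng.integers(1, 4, 300)
        top = explain_phenogroups(X, labels, seed=0)
        for g, frame in top.items():
            assert len(frame) == 3

    def test_random_labels_strong_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 10))
        labels = rng.integers(0, 2, 200)
        top = explain_phenogroups(X, labels, C_grid=(1e-4,),
                                  l1_ratios=(1.0,), seed=0)
        for frame in top.values():
            assert np.all(frame.attrs["all_coefs"] == 0.0)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            explain_phenogroups(np.zeros((50, 5)), np.ones(50))


class TestModelComparison:
    @pytest.fixture(scope="class")
    def surv(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        t_event = rng.exponential(1.0 / (0.01 * np.exp(0.8 * x)))
        c = rng.exponential(120, n)
        return pd.DataFrame({
            "x": x, "noise": noise,
            "time_to_event": np.minimum(t_event, c),
            "event_observed": (t_event <= c).astype(int),
        })

    def test_self_comparison_is_null(self, surv):
        res = compare_prognostic_models(
            surv, ["x"], ["x"], n_boot=50, seed=0,
            reference_phenogroup=None)
        assert res["z"] == 0.0
        assert res["c_index_A"] == res["c_index_B"]

    def test_true_predictor_beats_noise(self, surv):
        res = compare_prognostic_models(
            surv, ["x"], ["noise"], n_boot=100, seed=0,
            reference_phenogroup=None, return_samples=True)
        frac = np.mean(res["samples_A"] > res["samples_B"])
        assert frac >= 0.95
        assert res["z"] > 2.0

    def test_noise_model_concordance_near_chance(self, surv):
        res = compare_prognostic_models(
            surv, ["noise"], ["noise"], n_boot=50, seed=1,
            reference_phenogroup=None)
        assert res["c_index_A"] == pytest.approx(0.5, abs=0.03)

    def test_no_events_rejected(self, surv):
        dead = surv.assign(event_observed=0)
        with pytest.raises(ModelFitError, match="no events"):
            compare_prognostic_models(dead, ["x"], ["noise"], n_boot=5,
                                      reference_phenogroup=None)


class TestAdjustPvalues:
    def test_single_pvalue_unchanged(self):
        out = adjust_pvalues(pd.DataFrame({"p": [0.037]}))
        assert out["q"].iloc[0] == pytest.approx(0.037)

    def test_bh_step_up_hand_computed(self):
        out = adjust_pvalues(pd.DataFrame({"p": [0.01, 0.02, 0.03,
                                                 0.04]}))
        np.testing.assert_allclose(out["q"], [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        out = adjust_pvalues(pd.DataFrame({"p": [1.0, 1.0, 1.0]}))
        np.testing.assert_allclose(out["q"], 1.0)

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        out = adjust_pvalues(pd.DataFrame({"p": p}))
        assert (out["q"].to_numpy() >= p - 1e-15).all()
        order_p = np.argsort(p)
        q_sorted = out["q"].to_numpy()[order_p]
        assert (np.diff(q_sorted) >= -1e-15).all()

    def test_model_result_list_gains_q(self):
        t1 = pd.DataFrame({"term": ["a"], "p": [0.01]})
        t2 = pd.DataFrame({"term": ["b"], "p": [0.5]})
        r1 = ModelResult(table=t1, model_kind="logistic", n=10)
        r2 = ModelResult(table=t2, model_kind="logistic", n=10)
        adjust_pvalues([r1, r2])
        assert "q" in r1.table.columns
        assert r1.table["q"].iloc[0] >= 0.01
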