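"""Diffusion-IRT estimation, EAP scoring, and fit diagnostics."""
import copy

import numpy as np
import pandas as pd
import pytest

from emadiff import data_model as dm
from emadiff import ddm, diffirt, synthetic


class TestFit:
    def test_item_parameter_recovery(self, synth_medium, affect_fit):
        # correlations are invariant to the anchoring (location/scale) shift
        _, _, truth = synth_medium
        true = truth.items.set_index("item_id").loc[list(affect_fit.item_ids)]
        assert np.corrcoef(affect_fit.v, true["v"])[0, 1] >= 0.9
        assert np.corrcoef(affect_fit.a, true["a"])[0, 1] >= 0.9

    def test_two_items_rejected(self):
        occ = [
            dm.OccasionData("p", i, 1, {"a": 1, "b": 0}, {"a": 3.0, "b": 4.0})
            for i in range(60)
        ]
        with pytest.raises(ValueError, match="3 items"):
            diffirt.fit_item_parameters(occ)

    def test_likelihood_at_truth_below_fitted_maximum(
        self, synth_medium, affect_occasions, affect_fit
    ):
        # evaluating the marginal likelihood at the (anchored) generating
        # parameters must not beat the fitted maximum
        cfg, _, truth = synth_medium
        occ, _ = affect_occasions
        keys = {(o.person_id, o.occasion_id) for o in occ}
        tocc = truth.occasions
        mask = [
            (p, o) in keys
            for p, o in zip(tocc["person_id"], tocc["occasion_id"])
        ]
        sub = tocc[mask]
        m_th, m_lg = sub["theta"].mean(), sub["log_gamma"].mean()
        items = truth.items.set_index("item_id").loc[list(affect_fit.item_ids)]
        ll_truth = diffirt.marginal_loglik(
            occ, list(affect_fit.item_ids),
            v=items["v"].to_numpy() - m_th,
            a=items["a"].to_numpy() * np.exp(-m_lg),
            omega_theta=sub["theta"].std(),
            omega_gamma=sub["log_gamma"].std(),
        )
        assert affect_fit.loglik >= ll_truth - 2.0

    def test_loglik_invariant_to_row_and_item_relabeling(
        self, affect_occasions, affect_fit
    ):
        occ, _ = affect_occasions
        rows = occ[:400]
        ids = list(affect_fit.item_ids)
        base = diffirt.marginal_loglik(
            rows, ids, affect_fit.v, affect_fit.a,
            affect_fit.omega_theta, affect_fit.omega_gamma,
        )
        rng = np.random.default_rng(0)
        perm_rows = [rows[i] for i in rng.permutation(len(rows))]
        item_perm = rng.permutation(len(ids))
        ll_rows = diffirt.marginal_loglik(
            perm_rows, ids, affect_fit.v, affect_fit.a,
            affect_fit.omega_theta, affect_fit.omega_gamma,
        )
        ll_items = diffirt.marginal_loglik(
            rows, [ids[k] for k in item_perm],
            affect_fit.v[item_perm], affect_fit.a[item_perm],
            affect_fit.omega_theta, affect_fit.omega_gamma,
        )
        assert ll_rows == pytest.approx(base, abs=1e-8 * abs(base))
        assert ll_items == pytest.approx(base, abs=1e-8 * abs(base))


class TestScores:
    def test_theta_recovery_at_five_items(self, scores_with_truth):
        ok = scores_with_truth.dropna(subset=["theta", "theta_true"])
        assert np.corrcoef(ok["theta"], ok["theta_true"])[0, 1] >= 0.5

    def test_eap_means_anchored_near_zero(self, scores_with_truth):
        assert abs(np.nanmean(scores_with_truth["theta"])) < 0.05
        assert abs(np.nanmean(scores_with_truth["log_gamma"])) < 0.05

    def test_extreme_row_scores_remain_finite(self, affect_fit):
        occ = [
            dm.OccasionData(
                "p", 1, 1,
                {i: 1 for i in affect_fit.item_ids},
                {i: rt for i, rt in zip(affect_fit.item_ids, (2.0, 2, 3, 2, 3))},
            )
        ]
        s = diffirt.score_occasions(occ, affect_fit)[0]
        assert np.isfinite(s.theta) and np.isfinite(s.gamma)

    def test_abs_drift_is_mean_distance_to_difficulties(self):
        # theta = 0 against difficulties (-1,-0.5,0,0.5,1) averages to 0.6
        v = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        assert np.mean(np.abs(0.0 - v)) == pytest.approx(0.6)
        fit = diffirt.DiffIRTFit(
            items=[diffirt.DiffusionItemParams(f"i{k}", vv, 1.0)
                   for k, vv in enumerate(v)],
            omega_theta=1e-9, omega_gamma=1e-9, loglik=0.0, converged=True,
            n_rows=1, n_quad=3, kappa=0.9,
        )
        occ = [dm.OccasionData("p", 1, 1, {f"i{k}": 1 for k in range(5)},
                               {f"i{k}": 3.0 + k for k in range(5)})]
        s = diffirt.score_occasions(occ, fit)[0]
        # omega ~ 0 pins theta at 0, exposing the plug-in transformation
        assert s.abs_drift == pytest.approx(0.6, abs=1e-6)

    def test_kappa_profile_sensitivity(self, affect_occasions, affect_fit):
        # the nondecision-time profile is a stand-in; changing kappa must
        # mostly shift a common offset, not reorder the drift scores
        import dataclasses

        occ, _ = affect_occasions
        rows = occ[:600]
        s90 = diffirt.scores_to_frame(diffirt.score_occasions(rows, affect_fit))
        fit80 = dataclasses.replace(affect_fit, kappa=0.8)
        s80 = diffirt.scores_to_frame(diffirt.score_occasions(rows, fit80))
        ok = np.isfinite(s90.theta) & np.isfinite(s80.theta)
        rank = (
            pd.Series(s90.theta[ok]).rank().corr(pd.Series(s80.theta[ok]).rank())
        )
        assert rank > 0.9

    def test_boundary_outlier_rule_sets_missing(self, affect_occasions, affect_fit):
        occ, _ = affect_occasions
        scores = diffirt.score_occasions(occ[:300], affect_fit, outlier_iqr=0.8)
        flagged = [s for s in scores if s.outlier]
        assert flagged, "a tight rule must flag the low tail"
        assert all(np.isnan(s.log_gamma) and np.isnan(s.log_abs_drift) for s in flagged)
        default = diffirt.score_occasions(occ[:300], affect_fit)
        assert sum(s.outlier for s in default) <= len(flagged)


class TestDiagnostics:
    def test_qq_self_consistency(self, affect_occasions, affect_fit, affect_scores):
        # data simulated from the fitted model itself must sit on the line
        occ, _ = affect_occasions
        rng = np.random.default_rng(4)
        sim_occ = []
        smap = {(s.person_id, s.occasion_id): s for s in affect_scores}
        for o in occ:
            s = smap[(o.person_id, o.occasion_id)]
            if not np.isfinite(s.theta) or not np.isfinite(s.gamma):
                continue
            items = [i for i in affect_fit.item_ids if i in o.rts]
            h = [affect_fit.item_ids.index(i) for i in items]
            x, t = ddm.sample_responses(
                s.theta - affect_fit.v[h], s.gamma / affect_fit.a[h],
                np.full(len(h), s.ter), rng,
            )
            sim_occ.append(
                dm.OccasionData(o.person_id, o.occasion_id, o.day,
                                dict(zip(items, x.astype(int))),
                                dict(zip(items, t)))
            )
        qq = diffirt.qq_diagnostic(sim_occ, affect_fit, scores=affect_scores,
                                   rng=np.random.default_rng(5))
        med = qq[qq.percentile == 50]
        assert (med.observed - med.model).abs().max() < 0.25

    def test_qq_detects_constructed_shift(self, affect_occasions, affect_fit,
                                          affect_scores):
        occ, _ = affect_occasions
        shifted = []
        for o in occ:
            o2 = copy.deepcopy(o)
            o2.rts = {k: v + 2.0 for k, v in o.rts.items()}
            shifted.append(o2)
        qq = diffirt.qq_diagnostic(shifted, affect_fit, scores=affect_scores,
                                   rng=np.random.default_rng(5))
        med = qq[qq.percentile == 50]
        assert (med.observed - med.model).min() > 1.0

    def test_qq_quantiles_monotone(self, affect_occasions, affect_fit, affect_scores):
        occ, _ = affect_occasions
        qq = diffirt.qq_diagnostic(occ[:500], affect_fit, scores=affect_scores,
                                   rng=np.random.default_rng(6))
        for _, g in qq.groupby("item_id"):
            assert np.all(np.diff(g.sort_values("percentile")["observed"]) >= 0)
            assert np.all(np.diff(g.sort_values("percentile")["model"]) >= 0)

    def test_distance_difficulty_inverted_u(self, affect_fit):
        # expected RT peaks where the person drift meets the item difficulty
        for h in range(len(affect_fit.item_ids)):
            v, a = affect_fit.v[h], affect_fit.a[h]
            thetas = np.linspace(v - 2, v + 2, 81)
            ert = ddm.mean_decision_time(thetas - v, np.exp(0.0) / a)
            peak = thetas[np.argmax(ert)]
            assert peak == pytest.approx(v, abs=0.06)
            assert ert[0] < ert.max() and ert[-1] < ert.max()


class TestUnidimensionality:
    def test_one_factor_data_dominant_eigenvalue(self, affect_occasions):
        occ, _ = affect_occasions
        items = sorted({i for o in occ for i in o.binary_responses})
        X = pd.DataFrame(
            [[o.binary_responses.get(i, np.nan) for i in items] for o in occ],
            columns=items,
        )
        res = diffirt.unidimensionality_check(X)
        assert res.eigen_ratio > 3

    def test_independent_items_ratio_near_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.integers(0, 2, (2000, 5)), columns=list("abcde"))
        res = diffirt.unidimensionality_check(X)
        assert res.eigen_ratio < 1.5

    def test_duplicated_item_loads_at_unity(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 400)
        X = pd.DataFrame({"a": x, "b": x, "c": x})
        res = diffirt.unidimensionality_check(X)
        assert np.allclose(res.loadings, 1.0, atol=1e-3)

    def test_single_category_item_excluded(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.integers(0, 2, (300, 3)), columns=list("abc"))
        X["d"] = 1
        with pytest.warns(UserWarning, match="excluded"):
            res = diffirt.unidimensionality_check(X)
        assert res.excluded_items == ["d"]
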