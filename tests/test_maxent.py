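import numpy as np
import pytest
from scipy.optimize import brentq

from sdmshift import maxent
from sdmshift.features import FeatureSpec
from sdmshift.maxent import (
    aicc,
    evaluate_auc,
    fit_maxent,
    jackknife_importance,
    percent_contribution,
    predict,
    response_curve,
    training_gain,
    tune,
)


@pytest.fixture(scope="module")
def toy_1d(rng_module=None):
    """Presences concentrated at high x against a uniform background."""
    rng = np.random.default_rng(11)
    bg = rng.uniform(0, 1, (500, 1))
    pres = rng.beta(5, 1, (80, 1))  # skewed toward 1
    return pres, bg


class TestFitting:
    def test_huge_penalty_shrinks_everything_to_zero(self, toy_1d):
        pres, bg = toy_1d
        model = fit_maxent(pres, bg, "LQ", rm=1e6)
        assert model.n_nonzero == 0
        raw = predict(model, bg, link="raw")
        np.testing.assert_allclose(raw, raw[0])

    def test_positive_gradient_gives_positive_linear_coefficient(self, toy_1d):
        pres, bg = toy_1d
        model = fit_maxent(pres, bg, "L", rm=0.5)
        lin = [
            l
            for m, l in zip(model.expander.meta, model.coefficients)
            if m.cls == "L"
        ]
        assert lin[0] > 0

    def test_gibbs_fit_matches_brute_force_max_entropy(self):
        """Tiny discrete world: the weakly penalized Gibbs fit must agree with
        the exact maximum-entropy distribution subject to the empirical
        feature-mean constraint, solved independently through the 1-D dual."""
        cells = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        pres = np.array([[3.0], [4.0], [5.0], [4.0]])
        model = fit_maxent(pres, cells, "L", rm=1e-6)
        p_fit = predict(model, cells, link="raw")

        # oracle: p_i = exp(lam * f_i) / Z with f the same scaled feature,
        # lam chosen so the expectation matches the presence mean
        f = cells[:, 0] / 5.0
        target = np.mean(pres[:, 0] / 5.0)

        def moment_gap(lam):
            w = np.exp(lam * f)
            return (w @ f) / w.sum() - target

        lam = brentq(moment_gap, -100, 100)
        w = np.exp(lam * f)
        p_oracle = w / w.sum()
        np.testing.assert_allclose(p_fit, p_oracle, atol=1e-3)

    def test_no_presences_is_fatal(self, toy_1d):
        _, bg = toy_1d
        with pytest.raises(ValueError):
            fit_maxent(np.empty((0, 1)), bg, "L")

    def test_deterministic(self, toy_1d):
        pres, bg = toy_1d
        m1 = fit_maxent(pres, bg, "LQH", rm=1.0)
        m2 = fit_maxent(pres, bg, "LQH", rm=1.0)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)


class TestPrediction:
    def test_raw_sums_to_one_over_training_background(self, training_data):
        pres, bg, names = training_data
        model = fit_maxent(pres, bg, "LQH", rm=1.0, covariate_names=names)
        assert predict(model, bg, link="raw").sum() == pytest.approx(1.0, abs=1e-8)

    def test_links_are_rank_equivalent(self, training_data):
        pres, bg, names = training_data
        model = fit_maxent(pres, bg, "LQ", rm=1.0, covariate_names=names)
        raw = predict(model, bg, link="raw")
        logi = predict(model, bg, link="logistic")
        clog = predict(model, bg, link="cloglog")
        order = np.argsort(raw)
        # monotone transforms preserve the cell ranking (ties may appear
        # where the sigmoid links saturate in float precision)
        assert np.all(np.diff(logi[order]) >= 0)
        assert np.all(np.diff(clog[order]) >= 0)
        assert logi.min() >= 0 and logi.max() <= 1
        assert clog.min() >= 0 and clog.max() <= 1

    def test_missing_covariate_is_named(self, training_data):
        pres, bg, names = training_data
        model = fit_maxent(pres, bg, "L", covariate_names=names)
        from sdmshift.grids import GridSpec, LayerStack, RasterGrid
        from sdmshift.maxent import predict_raster

        spec = GridSpec(2, 2, 0.0, 2.0, 1.0)
        stack = LayerStack({"bio1": RasterGrid(spec, np.ones((2, 2)), "bio1")})
        with pytest.raises(KeyError, match="bio2"):
            predict_raster(model, stack)


class TestAUC:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties(self):
        assert evaluate_auc([0.5] * 4, [0.5] * 6) == 0.5

    def test_matches_exhaustive_pairwise_comparison(self):
        sp = np.array([0.9, 0.4, 0.6, 0.4])
        sb = np.array([0.2, 0.4, 0.7, 0.1])
        wins = sum(
            1.0 if p > b else (0.5 if p == b else 0.0) for p in sp for b in sb
        )
        assert evaluate_auc(sp, sb) == pytest.approx(wins / 16)

    def test_invariant_under_monotone_transform(self, rng):
        sp, sb = rng.random(30), rng.random(40)
        base = evaluate_auc(sp, sb)
        assert evaluate_auc(np.exp(3 * sp), np.exp(3 * sb)) == pytest.approx(base)


class TestTuning:
    def test_aicc_formula_fixture(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(2 * 3 + 200 + 24 / 46)

    def test_aicc_infinite_when_overparameterized(self):
        assert aicc(-10.0, 50, 50) == np.inf

    def test_grid_produces_one_candidate_per_combination(self, toy_1d):
        pres, bg = toy_1d
        result = tune(pres, bg, rm_grid=(0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4), fc_sets=("L",))
        assert len(result.candidates) == 8
        deltas = [c["delta_aicc"] for c in result.candidates]
        assert min(deltas) == 0
        assert result.best["delta_aicc"] == 0

    def test_single_candidate_is_selected(self, toy_1d):
        pres, bg = toy_1d
        result = tune(pres, bg, rm_grid=(1.0,), fc_sets=("L",))
        assert result.selected == 0

    def test_selection_invariant_to_candidate_order(self, toy_1d):
        pres, bg = toy_1d
        kw = dict(fc_sets=("L", "LQ"), n_hinge_knots=4)
        r1 = tune(pres, bg, rm_grid=(0.5, 2.0), **kw)
        r2 = tune(pres, bg, rm_grid=(2.0, 0.5), fc_sets=("LQ", "L"), n_hinge_knots=4)
        assert (r1.best["fc"], r1.best["rm"]) == (r2.best["fc"], r2.best["rm"])

    def test_sparsity_monotone_in_rm(self, training_data):
        pres, bg, names = training_data
        ks = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            model = fit_maxent(
                pres, bg, FeatureSpec(frozenset("LQH"), 8, 8), rm, covariate_names=names
            )
            ks.append(model.n_nonzero)
        assert all(b <= a for a, b in zip(ks, ks[1:]))


class TestImportance:
    def test_duplicated_covariate_has_no_leave_one_out_drop(self, rng):
        x = rng.random(300)
        bg = np.column_stack([x, x])
        xp = rng.beta(4, 1, 60)
        pres = np.column_stack([xp, xp])
        jk = jackknife_importance(pres, bg, "L", rm=1.0)
        full = jk["full_gain"]
        for stats in jk["variables"].values():
            assert full - stats["gain_without"] == pytest.approx(0.0, abs=1e-3)

    def test_informative_covariate_beats_noise(self, rng):
        n_bg, n_p = 500, 100
        bg = np.column_stack([rng.uniform(0, 1, n_bg), rng.uniform(0, 1, n_bg)])
        pres = np.column_stack([rng.beta(6, 1, n_p), rng.uniform(0, 1, n_p)])
        jk = jackknife_importance(pres, bg, "L", rm=1.0, covariate_names=["inf", "noise"])
        assert (
            jk["variables"]["inf"]["gain_with_only"]
            > jk["variables"]["noise"]["gain_with_only"]
        )
        model = fit_maxent(pres, bg, "L", 1.0, covariate_names=["inf", "noise"])
        pc = percent_contribution(model, pres, bg, seed=3)
        assert pc["inf"] > pc["noise"]

    def test_full_gain_at_least_best_single_gain(self, training_data):
        pres, bg, names = training_data
        jk = jackknife_importance(
            pres[:, :3], bg[:, :3], "L", rm=1.0, covariate_names=names[:3]
        )
        best_single = max(v["gain_with_only"] for v in jk["variables"].values())
        assert jk["full_gain"] >= best_single - 1e-6

    def test_single_covariate_contribution_is_100(self, toy_1d):
        pres, bg = toy_1d
        model = fit_maxent(pres, bg, "L", 1.0)
        pc = percent_contribution(model, pres, bg, seed=0)
        assert list(pc.values()) == [pytest.approx(100.0)]

    def test_contribution_sums_to_100_and_is_seed_stable(self, training_data):
        pres, bg, names = training_data
        model = fit_maxent(pres, bg, "LQ", 1.0, covariate_names=names)
        pc1 = percent_contribution(model, pres, bg, seed=5)
        pc2 = percent_contribution(model, pres, bg, seed=5)
        assert pc1 == pc2
        assert sum(pc1.values()) == pytest.approx(100.0, abs=1e-6)


class TestResponseCurves:
    def test_flat_when_all_coefficients_zero(self, toy_1d):
        pres, bg = toy_1d
        model = fit_maxent(pres, bg, "L", rm=1e6)
        _, ys = response_curve(model, "x0")
        np.testing.assert_allclose(ys, ys[0])

    def test_curve_bounded_for_sigmoid_links(self, training_data):
        pres, bg, names = training_data
        model = fit_maxent(pres, bg, "LQ", 1.0, covariate_names=names)
        for link in ("logistic", "cloglog"):
            _, ys = response_curve(model, names[0], link=link)
            assert ys.min() >= 0 and ys.max() <= 1

    def test_unknown_variable_errors(self, toy_1d):
        pres, bg = toy_1d
        model = fit_maxent(pres, bg, "L")
        with pytest.raises(KeyError):
            response_curve(model, "nope")

    def test_recovers_gaussian_optimum(self, world, species, suitability):
        """Virtual-species parameter recovery: the fitted response curve must
        peak near the programmed optimum of the dominant covariate."""
        from sdmshift import grids, niche, synth

        table = synth.sample_presences(suitability, species)
        X, ok = grids.extract_at_points(world, table)
        _, bg = niche.sample_background(world, n=1000, seed=55)
        model = fit_maxent(X[ok], bg, "LQ", 1.0, covariate_names=world.names)
        name = world.names[0]
        xs, ys = response_curve(model, name)
        peak = xs[np.argmax(ys)]
        opt = species.response_optima[name]
        span = model.expander.hi[0] - model.expander.lo[0]
        assert abs(peak - opt) <= 0.05 * span


def test_training_gain_positive_for_informative_model(training_data):
    pres, bg, names = training_data
    model = fit_maxent(pres, bg, "LQ", 1.0, covariate_names=names)
    assert training_gain(model, pres) > 0.2


def test_model_serialization_round_trip(tmp_path, toy_1d):
    import json

    pres, bg = toy_1d
    model = fit_maxent(pres, bg, "LQ", 1.0)
    path = tmp_path / "model.json"
    model.save(path)
    obj = json.loads(path.read_text())
    assert obj["feature_classes"] == "LQ"
    assert obj["rm"] == 1.0
    assert len(obj["coefficients"]) == model.n_nonzero
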