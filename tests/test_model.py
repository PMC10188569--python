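"""The L1-regularized Gibbs model: regularization schedule, solver
correctness against brute force, closed-form limits, output invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from maxsdm.features import FeatureMatrix, fit_feature_defs, transform_features
from maxsdm.model import (
    MaxentModel,
    fit_maxent,
    predict_cloglog,
    predict_raw,
    regularization_vector,
    train,
)
from maxsdm.samples import SampleMatrix
from .oracles import brute_force_min, random_tiny_instance


def sm(data, provenance="presence"):
    return SampleMatrix(pd.DataFrame(data), provenance)


def simple_design(m=100, n=300, seed=0, classes="L"):
    rng = np.random.default_rng(seed)
    p = sm({"x": rng.uniform(5, 10, m), "y": rng.uniform(0, 1, m)})
    b = sm({"x": rng.uniform(0, 10, n), "y": rng.uniform(0, 1, n)}, "background")
    defs = fit_feature_defs(p, b, classes=classes, n_knots=5)
    return transform_features(p, defs), transform_features(b, defs), defs


class TestRegularization:
    def test_linear_in_rm(self):
        fp, _, defs = simple_design()
        b1 = regularization_vector(defs, fp, rm=1.0)
        b2 = regularization_vector(defs, fp, rm=2.0)
        np.testing.assert_allclose(b2, 2 * b1)
        assert np.all(b1 > 0)

    def test_hinge_table_at_m100(self):
        rng = np.random.default_rng(1)
        data = {"x": rng.uniform(size=100)}
        p, b = sm(data), sm(data, "background")
        defs = fit_feature_defs(p, b, classes="H", n_knots=4)
        fp = transform_features(p, defs)
        beta = regularization_vector(defs, fp, rm=1.0)
        sd = np.maximum(fp.values.std(axis=0), 1 / 10)
        np.testing.assert_allclose(beta, 0.5 * sd / 10)

    def test_tables_clamped_beyond_range(self):
        rng = np.random.default_rng(2)
        data = {"x": rng.uniform(size=300)}
        p, b = sm(data), sm(data, "background")
        for classes, expected_class in (("L", 0.05), ("T", 1.0), ("H", 0.5)):
            defs = fit_feature_defs(p, b, classes=classes, n_knots=3)
            fp = transform_features(p, defs)
            beta = regularization_vector(defs, fp, rm=1.0)
            sd = np.maximum(fp.values.std(axis=0), 1 / np.sqrt(300))
            np.testing.assert_allclose(beta, expected_class * sd / np.sqrt(300))

    def test_constant_feature_uses_floor(self):
        # presences all share one x value -> sd 0, floored at 1/sqrt(m)
        p = sm({"x": np.full(25, 5.0)})
        b = sm({"x": np.linspace(0, 10, 50)}, "background")
        defs = fit_feature_defs(p, b, classes="L")
        fp = transform_features(p, defs)
        beta = regularization_vector(defs, fp, rm=1.0)
        assert np.all(beta > 0) and np.all(np.isfinite(beta))

    def test_needs_two_presences(self):
        p = sm({"x": [1.0]})
        b = sm({"x": [0.0, 1.0]}, "background")
        defs = fit_feature_defs(p, b, classes="L")
        with pytest.raises(ValueError):
            regularization_vector(defs, transform_features(p, defs), rm=1.0)


class TestClosedFormLimits:
    def test_full_shrinkage_gives_uniform_model(self):
        fp, fb, _ = simple_design()
        beta = np.full(fp.values.shape[1], 1e9)
        m = fit_maxent(fp, fb, beta)
        assert np.all(m.lam == 0)
        assert m.gain == pytest.approx(0.0, abs=1e-12)
        assert m.entropy == pytest.approx(np.log(m.n_background))
        raw = predict_raw(m, fb)
        np.testing.assert_allclose(raw, 1 / m.n_background)
        np.testing.assert_allclose(predict_cloglog(m, fb), 1 - np.exp(-1))

    def test_positive_coefficient_for_enriched_feature(self):
        """Presences concentrated at high feature values force lambda > 0,
        and the solver matches a 1-D dense grid search."""
        rng = np.random.default_rng(3)
        Fb = rng.uniform(size=(50, 1))
        Fp = rng.uniform(0.7, 1.0, size=(20, 1))
        defs = fit_feature_defs(
            sm({"x": Fp[:, 0]}), sm({"x": Fb[:, 0]}, "background"), classes="L"
        )
        beta = np.array([0.1])
        model = fit_maxent(
            FeatureMatrix(Fp, defs), FeatureMatrix(Fb, defs), beta, tol=1e-10
        )
        assert model.lam[0] > 0
        _, f_star = brute_force_min(Fp, Fb, beta)
        assert model.objective == pytest.approx(f_star, abs=1e-4)

    def test_empty_presence_rejected(self):
        fp, fb, defs = simple_design()
        empty = FeatureMatrix(np.empty((0, fp.values.shape[1])), defs)
        with pytest.raises(ValueError):
            fit_maxent(empty, fb, np.ones(fp.values.shape[1]))

    def test_beta_length_checked(self):
        fp, fb, _ = simple_design()
        with pytest.raises(ValueError):
            fit_maxent(fp, fb, np.ones(3 + fp.values.shape[1]))


class TestSolverOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_tiny_instances(self, seed):
        """Solver objective within 1e-3 of an exhaustive grid search."""
        Fp, Fb, beta = random_tiny_instance(seed)
        defs = fit_feature_defs(
            sm({f"v{j}": Fp[:, j] for j in range(Fp.shape[1])}),
            sm({f"v{j}": Fb[:, j] for j in range(Fb.shape[1])}, "background"),
            classes="L",
        )
        model = fit_maxent(
            FeatureMatrix(Fp, defs), FeatureMatrix(Fb, defs), beta,
            tol=1e-12, max_iter=100_000,
        )
        _, f_star = brute_force_min(Fp, Fb, beta)
        assert abs(model.objective - f_star) <= 1e-3


@pytest.fixture(scope="module")
def fitted():
    fp, fb, _ = simple_design(classes="LQTH")
    beta = regularization_vector(fp.defs, fp, rm=1.0)
    return fit_maxent(fp, fb, beta), fp, fb


class TestInvariants:

    def test_background_raw_sums_to_one(self, fitted):
        model, _, fb = fitted
        assert predict_raw(model, fb).sum() == pytest.approx(1.0, abs=1e-9)

    def test_gain_trace_nondecreasing(self, fitted):
        model, _, _ = fitted
        gains = [g for _, g, _ in model.gain_trace]
        assert len(gains) > 0
        assert all(b >= a - 1e-9 for a, b in zip(gains, gains[1:]))

    def test_entropy_bounds(self, fitted):
        model, _, _ = fitted
        assert 0 <= model.entropy <= np.log(model.n_background)

    def test_cloglog_monotone_in_raw(self, fitted):
        model, _, fb = fitted
        raw = predict_raw(model, fb)
        clog = predict_cloglog(model, fb)
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= 0)
        assert clog.min() > 0 and clog.max() < 1

    def test_raw_ranking_follows_linear_score(self, fitted):
        model, _, fb = fitted
        eta = fb.values @ model.lam
        np.testing.assert_array_equal(
            rankdata(predict_raw(model, fb)), rankdata(eta)
        )

    def test_shrinkage_monotone_in_rm(self, small_presence, small_background):
        """Total |lambda| never grows as the regularization multiplier does."""
        norms = []
        for rm in (0.5, 1.0, 2.0, 3.0, 5.0):
            m = train(small_presence, small_background, classes="LQ", rm=rm, n_knots=5)
            norms.append(np.abs(m.lam).sum())
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, small_presence, small_background):
        m = train(small_presence, small_background, classes="LH", rm=2.0, n_knots=4)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = MaxentModel.load(path)
        fm = transform_features(small_presence, m2.defs)
        np.testing.assert_allclose(
            predict_cloglog(m, transform_features(small_presence, m.defs)),
            predict_cloglog(m2, fm),
        )
        assert m2.m == m.m and m2.n_background == m.n_background
        assert m2.gain == pytest.approx(m.gain)
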