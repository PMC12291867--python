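"""Generalized dissimilarity modelling: I-spline basis, site-pair table,
monotone fit and contributions."""

import numpy as np
import pandas as pd
import pytest

from betadrivers import (
    DissimilarityMatrix,
    ValidationError,
    build_sitepair_table,
    env_dissimilarity,
    fit_gdm,
    geodesic_distance_matrix,
    ispline_basis,
    pairwise_sorensen,
    partial_response,
    predictor_contributions,
)


def dm_from(values, ids=None, metric="d"):
    values = np.asarray(values, float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DissimilarityMatrix(ids, metric, values)


def table_from_condensed(y, preds: dict):
    n = int((1 + np.sqrt(1 + 8 * len(y))) / 2)
    from scipy.spatial.distance import squareform

    resp = dm_from(squareform(np.asarray(y, float)))
    predictors = {k: dm_from(squareform(np.asarray(v, float))) for k, v in preds.items()}
    return build_sitepair_table(resp, predictors)


class TestISpline:
    def test_boundary_values_and_monotonicity(self, rng):
        values = rng.uniform(2.0, 9.0, 200)
        basis = ispline_basis(values, n_splines=3)
        lo, hi = basis.knots[0], basis.knots[-1]
        assert np.allclose(basis.evaluate(np.array([lo])), 0.0, atol=1e-12)
        assert np.allclose(basis.evaluate(np.array([hi])), 1.0, atol=1e-12)
        grid = np.linspace(lo, hi, 1000)
        b = basis.evaluate(grid)
        assert (np.diff(b, axis=0) >= -1e-10).all()

    def test_clamping_outside_knots(self, rng):
        basis = ispline_basis(rng.uniform(0, 1, 50))
        assert np.allclose(basis.evaluate(np.array([-5.0])), 0.0)
        assert np.allclose(basis.evaluate(np.array([5.0])), 1.0)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValidationError):
            ispline_basis(np.full(10, 3.0))


class TestSitePairTable:
    def test_row_counts(self, bundle):
        cm = bundle.communities["April"]
        resp = pairwise_sorensen(cm)
        geo = geodesic_distance_matrix(bundle.sites)
        table = build_sitepair_table(resp, {"geo": geo})
        assert len(table) == 1225  # 50 sites
        two = dm_from(np.array([[0, 0.3], [0.3, 0]]))
        assert len(build_sitepair_table(two, {"p": dm_from(np.array([[0, 1.0], [1.0, 0]]))})) == 1

    def test_content_is_order_independent(self, rng):
        x = rng.random((5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        ids = list("abcde")
        t1 = build_sitepair_table(dm_from(d, ids), {"p": dm_from(d * 0.5, ids)})
        perm = [3, 1, 4, 0, 2]
        t2 = build_sitepair_table(
            dm_from(d[np.ix_(perm, perm)], [ids[i] for i in perm]),
            {"p": dm_from((d * 0.5)[np.ix_(perm, perm)], [ids[i] for i in perm])},
        )
        key = lambda t: {tuple(sorted(i)): r for i, r in zip(t.index, t.to_numpy().tolist())}
        assert key(t1) == key(t2)

    def test_id_mismatch_rejected(self):
        a = dm_from(np.zeros((3, 3)), list("abc"))
        b = dm_from(np.zeros((3, 3)), list("abd"))
        with pytest.raises(ValidationError):
            build_sitepair_table(a, {"p": b})


class TestFit:
    def test_noiseless_link_recovery(self, rng):
        g = rng.uniform(0, 2, 300)
        y = 1 - np.exp(-(0.1 + 2.0 * g))
        table = pd.DataFrame({"y": y, "g": g})
        fit = fit_gdm(table)
        assert fit.explained > 99.0
        assert fit.converged

    def test_constant_response_yields_null_model(self):
        table = pd.DataFrame({"y": np.full(30, 0.4), "g": np.linspace(0, 1, 30)})
        fit = fit_gdm(table)
        assert fit.explained == 0.0
        assert np.allclose(fit.coefs["g"], 0.0)

    def test_shuffled_predictor_explains_little(self):
        rng = np.random.default_rng(42)
        g = rng.uniform(0, 2, 200)
        y = 1 - np.exp(-(0.1 + 2.0 * g))
        table = pd.DataFrame({"y": y, "g": rng.permutation(g)})
        assert fit_gdm(table).explained < 5.0

    def test_deviance_trace_non_increasing_and_mu_in_unit_interval(self, rng):
        g = rng.uniform(0, 1, 150)
        y = np.clip(1 - np.exp(-(0.2 + g)) + rng.normal(0, 0.05, 150), 0, 1)
        table = pd.DataFrame({"y": y, "g": g})
        fit = fit_gdm(table)
        trace = np.array(fit.deviance_trace)
        assert (np.diff(trace) <= 1e-9).all()
        mu = fit.predict(table)
        assert (mu > 0).all() and (mu < 1).all()
        assert fit.intercept >= 0 and all((w >= 0).all() for w in fit.coefs.values())

    def test_invariant_to_affine_predictor_rescaling(self, rng):
        g = rng.uniform(0, 2, 200)
        y = np.clip(1 - np.exp(-(0.1 + 1.5 * g)) + rng.normal(0, 0.03, 200), 0, 1)
        f1 = fit_gdm(pd.DataFrame({"y": y, "g": g}))
        f2 = fit_gdm(pd.DataFrame({"y": y, "g": 100.0 * g + 7.0}))
        assert f1.deviance == pytest.approx(f2.deviance, abs=1e-6)


class TestContributions:
    def test_single_active_predictor_gets_all(self, rng):
        g = rng.uniform(0, 2, 200)
        y = 1 - np.exp(-(0.1 + 2.0 * g))
        noise = rng.permutation(g)
        fit = fit_gdm(pd.DataFrame({"y": y, "g": g, "noise": noise}))
        contrib = predictor_contributions(fit)
        assert contrib.loc["g", "contribution_pct"] > 95.0
        assert contrib["contribution_pct"].sum() == pytest.approx(100.0)

    def test_partial_response_boundaries(self, rng):
        g = rng.uniform(0, 2, 200)
        y = 1 - np.exp(-(0.1 + 2.0 * g))
        fit = fit_gdm(pd.DataFrame({"y": y, "g": g}))
        grid = np.linspace(g.min(), g.max(), 200)
        curve = partial_response(fit, "g", grid)["f"].to_numpy()
        assert curve[0] == pytest.approx(0.0, abs=1e-12)
        assert curve[-1] == pytest.approx(sum(fit.coefs["g"]), abs=1e-10)
        assert (np.diff(curve) >= -1e-10).all()
        with pytest.raises(ValidationError):
            partial_response(fit, "nope", grid)


def test_env_signal_dominates_on_filtered_community(bundle):
    """With the generator's default (filtering-dominated) regime the
    environmental dissimilarity out-contributes geographic distance."""
    cm = bundle.communities["April"]
    resp = pairwise_sorensen(cm)
    geo = geodesic_distance_matrix(bundle.sites)
    ed = env_dissimilarity(bundle.env["April"])
    fit = fit_gdm(build_sitepair_table(resp, {"geographic": geo, "environment": ed}))
    contrib = predictor_contributions(fit)
    assert (
        contrib.loc["environment", "contribution_pct"]
        > contrib.loc["geographic", "contribution_pct"]
    )
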