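import numpy as np
import pandas as pd
import pytest

from ecoredundancy.gdm import (
    GEO,
    build_site_pairs,
    fit_gdm,
    ispline_basis,
    partition_deviance,
    predict_dissimilarity,
    predicted_matrix,
    predictor_importance,
    rgb_ordination,
)


def _env(n, rng, gradient=True):
    x = np.linspace(0, 3, n) if gradient else rng.random(n) * 3
    return pd.DataFrame(
        {"p": x, "x": rng.random(n) * 10, "y": rng.random(n) * 10},
        index=[f"s{i}" for i in range(n)],
    )


def _pairs_from_transform(env, transform, noise=0.0, rng=None):
    x = env["p"].to_numpy()
    d = 1 - np.exp(-np.abs(transform(x)[:, None] - transform(x)[None, :]))
    if noise and rng is not None:
        d = np.clip(d + rng.normal(0, noise, d.shape), 0, 1)
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0)
    dm = pd.DataFrame(d, index=env.index, columns=env.index)
    return build_site_pairs(dm, env, ["p"])


class TestISpline:
    def test_bounds_and_monotonicity(self):
        x = np.linspace(-2, 7, 200)
        b = ispline_basis(x)
        assert np.allclose(b[0], 0) and np.allclose(b[-1], 1)
        assert (np.diff(b, axis=0) >= -1e-12).all()

    def test_three_functions(self):
        assert ispline_basis(np.linspace(0, 1, 10)).shape == (10, 3)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ispline_basis(np.ones(5))

    def test_clamping_outside_knots(self):
        knots = np.array([0.0, 0.5, 1.0])
        b = ispline_basis(np.array([-5.0, 5.0]), knots)
        assert np.allclose(b[0], 0) and np.allclose(b[1], 1)


class TestSitePairs:
    def test_pair_count_and_symmetric_content(self, rng):
        env = _env(6, rng)
        dm = pd.DataFrame(
            np.zeros((6, 6)), index=env.index, columns=env.index
        )
        pairs = build_site_pairs(dm, env, ["p"])
        assert len(pairs) == 15  # n(n-1)/2

    def test_zero_distance_for_identical_coordinates(self):
        env = pd.DataFrame(
            {"p": [0.0, 1.0], "x": [2.0, 2.0], "y": [3.0, 3.0]}, index=["a", "b"]
        )
        dm = pd.DataFrame([[0, 0.5], [0.5, 0]], index=["a", "b"], columns=["a", "b"])
        pairs = build_site_pairs(dm, env, ["p"])
        assert pairs[GEO].iloc[0] == 0.0

    def test_missing_site_named(self, rng):
        env = _env(4, rng).drop(index="s2")
        dm = pd.DataFrame(np.zeros((4, 4)), index=[f"s{i}" for i in range(4)],
                          columns=[f"s{i}" for i in range(4)])
        with pytest.raises(KeyError, match="s2"):
            build_site_pairs(dm, env, ["p"])


class TestFit:
    def test_all_zero_dissimilarity_degenerate(self, rng):
        env = _env(10, rng)
        dm = pd.DataFrame(np.zeros((10, 10)), index=env.index, columns=env.index)
        pairs = build_site_pairs(dm, env, ["p"])
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert all(np.allclose(c, 0, atol=1e-6) for c in fit.coefficients.values())
        assert fit.deviance_explained == 0.0

    def test_noiseless_recovery(self, rng):
        env = _env(200, rng)
        pairs = _pairs_from_transform(env, lambda x: x)
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        assert fit.deviance_explained > 95.0
        grid = np.linspace(0, 3, 60)
        f = fit.transform("p", grid)
        scale = np.sum(f * grid) / np.sum(f * f)
        assert np.sqrt(np.mean((scale * f - grid) ** 2)) < 0.05

    def test_permuted_response_destroys_signal(self, rng):
        env = _env(200, rng)
        pairs = _pairs_from_transform(env, lambda x: x)
        pairs["d"] = rng.permutation(pairs["d"].to_numpy())
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        assert fit.deviance_explained < 2.0

    def test_coefficients_non_negative(self, rng):
        env = _env(60, rng)
        pairs = _pairs_from_transform(env, np.sqrt, noise=0.05, rng=rng)
        fit = fit_gdm(pairs, ["p"])
        assert fit.intercept >= 0
        assert all((c >= 0).all() for c in fit.coefficients.values())

    def test_nested_deviance_monotone(self, rng):
        env = _env(80, rng)
        pairs = _pairs_from_transform(env, lambda x: x, noise=0.05, rng=rng)
        full = fit_gdm(pairs, ["p"], include_geo=True)
        env_only = fit_gdm(pairs, ["p"], include_geo=False)
        geo_only = fit_gdm(pairs, [], include_geo=True)
        assert full.deviance_explained >= env_only.deviance_explained - 1e-6
        assert full.deviance_explained >= geo_only.deviance_explained - 1e-6

    def test_too_few_pairs(self, rng):
        env = _env(4, rng)
        pairs = _pairs_from_transform(env, lambda x: x)
        with pytest.raises(ValueError, match="pairs"):
            fit_gdm(pairs, ["p"])


class TestImportance:
    def test_coefficient_sum(self, rng):
        env = _env(50, rng)
        pairs = _pairs_from_transform(env, lambda x: x)
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        imp = predictor_importance(fit)
        assert imp.loc["p", "importance"] == pytest.approx(
            fit.coefficients["p"].sum()
        )
        assert imp["share"].sum() == pytest.approx(1.0)

    def test_zero_coefficients_zero_importance(self, rng):
        env = _env(50, rng)
        env["junk"] = rng.random(50)
        pairs = _pairs_from_transform(env, lambda x: x)
        # rebuild with junk predictor included
        x = env["p"].to_numpy()
        d = 1 - np.exp(-np.abs(x[:, None] - x[None, :]))
        dm = pd.DataFrame(d, index=env.index, columns=env.index)
        pairs = build_site_pairs(dm, env, ["p", "junk"])
        fit = fit_gdm(pairs, ["p", "junk"], include_geo=False)
        imp = predictor_importance(fit)
        assert imp.loc["junk", "share"] < 0.05
        assert imp.loc["p", "share"] > 0.9


class TestPartition:
    def test_identity(self, rng):
        env = _env(60, rng)
        pairs = _pairs_from_transform(env, lambda x: x, noise=0.03, rng=rng)
        part = partition_deviance(pairs, ["p"])
        assert part.unique_env + part.unique_geo + part.shared == pytest.approx(
            part.full, abs=1e-9
        )

    def test_environment_only_turnover(self, rng):
        # p is spatially unstructured -> geography explains ~nothing
        env = _env(80, rng, gradient=False)
        pairs = _pairs_from_transform(env, lambda x: x)
        part = partition_deviance(pairs, ["p"])
        assert part.unique_geo < 2.0
        assert part.unique_env > 50.0

    def test_confounded_gradient_shared(self, rng):
        # predictor perfectly aligned with the x coordinate: geography
        # and environment explain the same deviance
        n = 60
        env = pd.DataFrame(
            {
                "p": np.linspace(0, 3, n),
                "x": np.linspace(0, 30, n),
                "y": np.zeros(n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        pairs = _pairs_from_transform(env, lambda x: x)
        part = partition_deviance(pairs, ["p"])
        assert part.shared == pytest.approx(part.full, abs=5.0)
        assert abs(part.unique_env) < 5.0 and abs(part.unique_geo) < 5.0


class TestPredict:
    def test_identical_sites_intercept_only(self, rng):
        env = _env(30, rng)
        pairs = _pairs_from_transform(env, lambda x: x, noise=0.02, rng=rng)
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        same = pd.DataFrame({"site_i": ["a"], "site_j": ["a"], "d": [0.0],
                             GEO: [0.0], "p_i": [1.0], "p_j": [1.0]})
        pred = predict_dissimilarity(fit, same)
        assert pred[0] == pytest.approx(1 - np.exp(-fit.intercept))

    def test_monotone_in_separation(self, rng):
        env = _env(50, rng)
        pairs = _pairs_from_transform(env, lambda x: x)
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        seps = np.linspace(0, 3, 20)
        table = pd.DataFrame({
            "site_i": "a", "site_j": "b", "d": 0.0, GEO: 0.0,
            "p_i": np.zeros(20), "p_j": seps,
        })
        pred = predict_dissimilarity(fit, table)
        assert (np.diff(pred) >= -1e-12).all()

    def test_extrapolation_clamped_with_warning(self, rng):
        env = _env(30, rng)
        pairs = _pairs_from_transform(env, lambda x: x, noise=0.02, rng=rng)
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        out = pd.DataFrame({"site_i": ["a"], "site_j": ["b"], "d": [0.0],
                            GEO: [0.0], "p_i": [-99.0], "p_j": [99.0]})
        with pytest.warns(RuntimeWarning, match="clamped"):
            predict_dissimilarity(fit, out)

    def test_unknown_predictor_errors(self, rng):
        env = _env(30, rng)
        pairs = _pairs_from_transform(env, lambda x: x, noise=0.02, rng=rng)
        fit = fit_gdm(pairs, ["p"], include_geo=False)
        with pytest.raises(KeyError):
            predict_dissimilarity(fit, pairs.drop(columns=["p_i"]))


class TestRGB:
    def test_all_equal_predictions_uniform_grey(self):
        n = 6
        m = np.full((n, n), 0.4)
        np.fill_diagonal(m, 0.0)
        pred = pd.DataFrame(m, index=range(n), columns=range(n))
        rgb = rgb_ordination(pred)
        # the equidistant simplex has no dominant axis; every channel is
        # either constant 0.5 or spans [0,1] symmetrically
        assert ((rgb[["R", "G", "B"]] >= 0) & (rgb[["R", "G", "B"]] <= 1)).all().all()

    def test_one_dimensional_gradient_monotone_channel(self):
        # linear 1D distances embed exactly on the first axis
        x = np.linspace(0, 1, 25)
        pm = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        with pytest.warns(RuntimeWarning, match="positive ordination axes"):
            rgb = rgb_ordination(pm)
        r = rgb["R"].to_numpy()  # sites are ordered along the gradient
        assert (np.diff(r) >= -1e-9).all() or (np.diff(r) <= 1e-9).all()

    def test_channels_in_unit_interval(self, rng):
        env = _env(20, rng)
        pairs = _pairs_from_transform(env, lambda x: x, noise=0.05, rng=rng)
        fit = fit_gdm(pairs, ["p"])
        pm = predicted_matrix(fit, pairs, list(env.index))
        rgb = rgb_ordination(pm)
        assert ((rgb[["R", "G", "B"]] >= 0) & (rgb[["R", "G", "B"]] <= 1)).all().all()

    def test_few_axes_warns_and_fills_half(self):
        # 1D configuration -> only 1 positive eigenvalue
        x = np.linspace(0, 1, 5)
        m = np.abs(x[:, None] - x[None, :])
        pred = pd.DataFrame(m, index=range(5), columns=range(5))
        with pytest.warns(RuntimeWarning, match="positive ordination axes"):
            rgb = rgb_ordination(pred)
        assert np.allclose(rgb["B"], 0.5)
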