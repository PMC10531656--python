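import numpy as np
import pandas as pd
import pytest

from ecoredundancy.alpha import (
    NullModelConfig,
    functional_richness,
    ses_functional_richness,
    shannon_heterogeneity,
    species_richness,
    swap_randomize,
    vif_screen,
)

from .conftest import planar_space


def _community(mat, species=None):
    mat = np.asarray(mat)
    species = species or [f"sp{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(
        mat, index=[f"site{i}" for i in range(mat.shape[0])], columns=species
    )


class TestRichness:
    def test_row_sums(self):
        c = _community([[0, 0, 0], [1, 1, 1], [1, 0, 1]])
        assert species_richness(c).tolist() == [0, 3, 2]

    def test_column_permutation_invariant(self, rng):
        c = _community(rng.integers(0, 2, (6, 10)))
        perm = rng.permutation(c.columns)
        assert (species_richness(c[perm]).to_numpy() == species_richness(c).to_numpy()).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            species_richness(_community([[0, 2]]))


class TestFunctionalRichness:
    def test_full_pool_is_one(self, rng):
        pts = rng.normal(size=(10, 2))
        space = planar_space(pts)
        c = _community(np.ones((1, 10), dtype=int), species=space.species)
        assert functional_richness(c, space, m_axes=2).iloc[0] == pytest.approx(1.0)

    def test_unit_square_quarter_of_pool(self):
        # pool: corners of a 2x2 square (area 4); site: unit square (area 1)
        pool = np.array(
            [[0, 0], [2, 0], [0, 2], [2, 2], [1, 0], [0, 1], [1, 1]], dtype=float
        )
        space = planar_space(pool)
        occ = np.zeros((1, 7), dtype=int)
        occ[0, [0, 4, 5, 6]] = 1  # (0,0),(1,0),(0,1),(1,1)
        c = _community(occ, species=space.species)
        assert functional_richness(c, space, m_axes=2).iloc[0] == pytest.approx(0.25)

    def test_too_few_or_degenerate_is_nan(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1]], dtype=float)
        space = planar_space(pts)
        collinear = _community([[1, 1, 1, 0, 0]], species=space.species)
        assert np.isnan(functional_richness(collinear, space, m_axes=2).iloc[0])
        few = _community([[1, 1, 0, 0, 0]], species=space.species)
        assert np.isnan(functional_richness(few, space, m_axes=2).iloc[0])

    def test_monotone_in_species_addition(self, rng):
        pts = rng.normal(size=(12, 3))
        space = planar_space(pts)
        occ = np.zeros(12, dtype=int)
        occ[:5] = 1
        base = functional_richness(
            _community(occ[None, :], species=space.species), space, m_axes=3
        ).iloc[0]
        for j in range(5, 12):
            grown = occ.copy()
            grown[j] = 1
            v = functional_richness(
                _community(grown[None, :], species=space.species), space, m_axes=3
            ).iloc[0]
            assert v >= base - 1e-12

    def test_in_unit_interval(self, rng):
        pts = rng.normal(size=(15, 3))
        space = planar_space(pts)
        c = _community(rng.integers(0, 2, (20, 15)), species=space.species)
        fric = functional_richness(c, space, m_axes=3)
        ok = fric.dropna()
        assert ((ok >= 0) & (ok <= 1 + 1e-12)).all()

    def test_monte_carlo_oracle_3d(self, rng):
        from .conftest import mc_hull_volume
        from ecoredundancy.alpha import _hull_volume_or_nan

        for seed in range(3):
            pts = np.random.default_rng(seed).normal(size=(12, 3))
            exact = _hull_volume_or_nan(pts)
            mc = mc_hull_volume(pts, n_samples=200_000, seed=seed)
            assert mc == pytest.approx(exact, rel=0.02)


class TestSwapNull:
    def test_margins_preserved(self, rng):
        c = _community(rng.integers(0, 2, (15, 12)))
        r = swap_randomize(c, NullModelConfig(seed=1))
        assert (r.sum(axis=0) == c.sum(axis=0)).all()
        assert (r.sum(axis=1) == c.sum(axis=1)).all()
        assert r.to_numpy().max() <= 1 and r.to_numpy().min() >= 0

    def test_identity_two_by_two_states(self):
        # only two matrices share the margins of I2: itself and the
        # anti-diagonal; the chain must stay within that pair
        c = _community(np.eye(2, dtype=int))
        seen = set()
        for seed in range(20):
            r = swap_randomize(c, NullModelConfig(seed=seed, burn_in=101))
            key = tuple(r.to_numpy().ravel())
            assert key in {(1, 0, 0, 1), (0, 1, 1, 0)}
            seen.add(key)
        assert len(seen) == 2  # both checkerboard states get visited

    def test_full_row_forced(self, rng):
        mat = rng.integers(0, 2, (6, 8))
        mat[2, :] = 1
        c = _community(mat)
        r = swap_randomize(c, NullModelConfig(seed=7))
        assert (r.iloc[2] == 1).all()

    def test_seeded_determinism(self, rng):
        c = _community(rng.integers(0, 2, (10, 10)))
        a = swap_randomize(c, NullModelConfig(seed=3))
        b = swap_randomize(c, NullModelConfig(seed=3))
        assert a.equals(b)


class TestSES:
    def test_richness_invariant_under_swaps(self, rng):
        # row sums never change, so a richness 'metric' has null SD 0
        c = _community(rng.integers(0, 2, (8, 10)))
        base = species_richness(c)
        for seed in range(10):
            r = swap_randomize(c, NullModelConfig(seed=seed))
            assert (species_richness(r) == base).all()

    def test_ses_zero_when_observed_equals_null_mean(self, rng):
        pts = rng.normal(size=(10, 2))
        space = planar_space(pts)
        # a community where every site holds the full pool: the null
        # model cannot move anything, so sd=0 -> NaN with warning
        c = _community(np.ones((4, 10), dtype=int), species=space.species)
        with pytest.warns(RuntimeWarning, match="zero null SD"):
            out = ses_functional_richness(
                c, space, m_axes=2, cfg=NullModelConfig(n_randomizations=5, seed=0)
            )
        assert out["SES_FRic"].isna().all()

    def test_ses_values_finite_on_random_data(self, rng):
        pts = rng.normal(size=(12, 2))
        space = planar_space(pts)
        c = _community(rng.integers(0, 2, (10, 12)), species=space.species)
        out = ses_functional_richness(
            c, space, m_axes=2, cfg=NullModelConfig(n_randomizations=29, seed=0)
        )
        assert len(out) == 10
        assert (out["null_sd"].dropna() >= 0).all()

    def test_nrand_validation(self):
        with pytest.raises(ValueError, match="n_randomizations"):
            NullModelConfig(n_randomizations=1)


class TestShannon:
    def test_single_class_zero(self):
        assert shannon_heterogeneity([1.0, 0, 0, 0]) == 0.0

    def test_four_equal_classes(self):
        assert shannon_heterogeneity([0.25] * 4) == pytest.approx(np.log(4))

    def test_two_equal_classes(self):
        assert shannon_heterogeneity([0.5, 0.5, 0, 0, 0]) == pytest.approx(np.log(2))

    def test_renormalization(self):
        # shares not summing to one are renormalized
        assert shannon_heterogeneity([0.2, 0.2]) == pytest.approx(np.log(2))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="positive"):
            shannon_heterogeneity([0.0, 0.0])

    def test_frame_input(self, rng):
        df = pd.DataFrame(rng.dirichlet(np.ones(4), size=5))
        h = shannon_heterogeneity(df)
        assert len(h) == 5 and (h >= 0).all() and (h <= np.log(4) + 1e-12).all()


class TestVIF:
    def test_orthogonal_predictors_retained(self):
        n = 40
        env = pd.DataFrame(
            {
                "a": np.sin(np.arange(n)),
                "b": np.cos(np.arange(n) * 2.1),
                "c": np.arange(n) % 5,
            }
        )
        retained, trace = vif_screen(env, ["a", "b", "c"])
        assert retained == ["a", "b", "c"] and trace.empty

    def test_duplicate_column_dropped_with_infinite_vif(self, rng):
        env = pd.DataFrame({"a": rng.normal(size=30)})
        env["b"] = env["a"]
        env["c"] = rng.normal(size=30)
        retained, trace = vif_screen(env, ["a", "b", "c"])
        assert len(retained) == 2 and "c" in retained
        assert np.isinf(trace["vif"].iloc[0])

    def test_compositional_closure_dropped(self, rng):
        cover = rng.dirichlet(np.ones(5), size=50)
        env = pd.DataFrame(cover, columns=list("abcde"))
        retained, trace = vif_screen(env, list("abcde"))
        assert len(retained) < 5  # exact linear dependence forces a drop

    def test_needs_two_predictors(self, rng):
        env = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            vif_screen(env, ["a"])
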