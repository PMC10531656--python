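import numpy as np
import pandas as pd
import pytest

from ecoredundancy.trait_space import TraitSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_traits():
    """Five species: A and B share all traits; the rest are distinct."""
    return pd.DataFrame(
        {
            "body_size_class": ["31-40", "31-40", "20-30", ">60", "41-50"],
            "voltinism_class": ["1", "1", "2", "1", "3"],
            "overwintering_stage": ["egg", "egg", "larvae", "pupae", "adult"],
            "diet": [
                "monophagous",
                "monophagous",
                "polyphagous",
                "broad oligophagous",
                "polyphagous",
            ],
        },
        index=pd.Index(["A", "B", "C", "D", "E"], name="species"),
    )


def planar_space(points: np.ndarray, species=None) -> TraitSpace:
    """TraitSpace wrapper around explicit planar coordinates (test helper)."""
    points = np.asarray(points, dtype=float)
    if species is None:
        species = [f"sp{i}" for i in range(len(points))]
    coords = pd.DataFrame(
        points, index=species, columns=[f"pcoa_{i + 1}" for i in range(points.shape[1])]
    )
    from scipy.spatial.distance import pdist, squareform

    d = pd.DataFrame(squareform(pdist(points)), index=species, columns=species)
    return TraitSpace(
        species=list(species),
        gower=d,
        coordinates=coords,
        eigenvalues=np.ones(points.shape[1]),
        full_coordinates=coords,
    )


@pytest.fixture
def default_dataset():
    from ecoredundancy.synthetic import make_benchmark_dataset

    return make_benchmark_dataset("default", seed=42)


def mc_hull_volume(points: np.ndarray, n_samples: int, seed: int = 0) -> float:
    """Monte-Carlo rejection estimate of a convex hull volume (oracle).

    Independent of the qhull-based implementation: samples the bounding
    box and tests facet inequalities of a Delaunay triangulation-free
    formulation via scipy.spatial.ConvexHull equations only to get the
    half-spaces; containment is a pure linear test.
    """
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, points.shape[1]))
    inside = (samples @ hull.equations[:, :-1].T + hull.equations[:, -1] <= 1e-12).all(
        axis=1
    )
    return box * inside.mean()


def mc_intersection_volume(
    pa: np.ndarray, pb: np.ndarray, n_samples: int, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the volume of the intersection of two hulls."""
    from scipy.spatial import ConvexHull

    ha, hb = ConvexHull(pa), ConvexHull(pb)
    lo = np.maximum(pa.min(axis=0), pb.min(axis=0))
    hi = np.minimum(pa.max(axis=0), pb.max(axis=0))
    if (hi <= lo).any():
        return 0.0
    box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, pa.shape[1]))
    ina = (samples @ ha.equations[:, :-1].T + ha.equations[:, -1] <= 1e-12).all(axis=1)
    inb = (samples @ hb.equations[:, :-1].T + hb.equations[:, -1] <= 1e-12).all(axis=1)
    return box * (ina & inb).mean()
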