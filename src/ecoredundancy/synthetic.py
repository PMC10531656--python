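"""Synthetic landscapes, species pools and communities.

Stand-in generator for the atlas-style inputs: a rectangular grid of
sites with a latitudinal temperature gradient and compositional land
cover, a trait-structured species pool with Gaussian thermal niches,
and Bernoulli presence/absence communities whose occupancy probability
is

    p_ij = baseline_j * exp(-(T_i - opt_j)^2 / (2 * breadth_j^2)).

Every draw is seeded, so identical configurations reproduce identical
datasets.  Benchmark presets bundle community, traits, environment and
the generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alpha import shannon_heterogeneity
from .trait_space import (
    BODY_SIZE_CLASSES,
    DIET_CLASSES,
    OVERWINTERING_STAGES,
    TRAIT_COLUMNS,
    VOLTINISM_CLASSES,
)

__all__ = [
    "COVER_CLASSES",
    "LandscapeConfig",
    "SpeciesPoolConfig",
    "SyntheticDataset",
    "generate_landscape",
    "generate_species_pool",
    "generate_communities",
    "make_benchmark_dataset",
    "PRESETS",
]

COVER_CLASSES = ("forest", "cropland", "grassland", "other", "water", "settlement")

# multiplicative response of each cover class's Dirichlet weight to the
# warm end of the gradient (confounds covers with temperature on purpose)
_COVER_WARM_SLOPE = {
    "forest": -1.5,
    "cropland": 2.0,
    "grassland": -0.5,
    "other": -1.0,
    "water": 0.0,
    "settlement": 1.0,
}

_CELL_KM = 10.0


class InvalidConfigError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Grid landscape with a latitudinal temperature gradient."""

    n_sites: int = 120
    grid_shape: tuple[int, int] = (12, 10)
    temp_range: tuple[float, float] = (4.0, 16.0)
    temp_noise_sd: float = 0.5
    cover_concentration: tuple[float, ...] = (2.0, 2.0, 2.0, 1.0, 1.0, 1.0)
    cover_gradient: float = 1.0  # 0 removes the cover-temperature confound
    pop_scale: float = 10_000.0
    elev_params: tuple[float, float] = (200.0, 80.0)
    shuffle_temperature: bool = False  # decouple temperature from geography
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if self.n_sites <= 0:
            raise InvalidConfigError("n_sites must be positive")
        if rows * cols != self.n_sites:
            raise InvalidConfigError(
                f"n_sites={self.n_sites} must equal rows*cols={rows * cols}"
            )
        if not self.temp_range[0] < self.temp_range[1]:
            raise InvalidConfigError("temp_range must satisfy min < max")
        if len(self.cover_concentration) != len(COVER_CLASSES):
            raise InvalidConfigError(
                f"need {len(COVER_CLASSES)} cover concentration weights"
            )
        if any(w <= 0 for w in self.cover_concentration):
            raise InvalidConfigError("cover concentration weights must be positive")
        if self.pop_scale <= 0:
            raise InvalidConfigError("pop_scale must be positive")


@dataclass(frozen=True)
class SpeciesPoolConfig:
    """Trait-structured species pool with Gaussian thermal niches."""

    n_species: int = 57
    trait_level_probs: dict = field(
        default_factory=lambda: {
            "body_size_class": (0.25, 0.30, 0.25, 0.15, 0.05),
            "voltinism_class": (0.45, 0.35, 0.12, 0.05, 0.03),
            "overwintering_stage": (0.20, 0.45, 0.25, 0.10),
            "diet": (0.25, 0.45, 0.30),
        }
    )
    niche_breadth_range: tuple[float, float] = (2.0, 6.0)
    optimum_range: tuple[float, float] | None = None  # default: landscape range
    detection_baseline: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 5:
            raise InvalidConfigError("n_species must be at least 5")
        levels = dict(
            zip(
                TRAIT_COLUMNS,
                (BODY_SIZE_CLASSES, VOLTINISM_CLASSES, OVERWINTERING_STAGES, DIET_CLASSES),
            )
        )
        for trait, probs in self.trait_level_probs.items():
            if trait not in levels:
                raise InvalidConfigError(f"unknown trait {trait!r}")
            if len(probs) != len(levels[trait]) or not probs:
                raise InvalidConfigError(
                    f"trait {trait!r} needs {len(levels[trait])} level probabilities"
                )
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise InvalidConfigError(f"probabilities for {trait!r} must sum to 1")
        if not 0 < self.detection_baseline <= 1:
            raise InvalidConfigError("detection_baseline must be in (0, 1]")
        if not 0 < self.niche_breadth_range[0] <= self.niche_breadth_range[1]:
            raise InvalidConfigError("niche_breadth_range must be positive and ordered")


def generate_landscape(cfg: LandscapeConfig) -> pd.DataFrame:
    """One environment row per grid cell.

    Temperature decreases (in expectation) with the row index — a
    latitude proxy — with Gaussian noise on top; land-cover fractions
    are Dirichlet draws whose class weights shift smoothly along the
    gradient; population is log-normal; coordinates are cell centroids.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    row_idx, col_idx = np.divmod(np.arange(cfg.n_sites), cols)
    tmin, tmax = cfg.temp_range
    frac = row_idx / max(rows - 1, 1)
    temp_expect = tmax - (tmax - tmin) * frac
    temperature = temp_expect + rng.normal(0.0, cfg.temp_noise_sd, cfg.n_sites)
    if cfg.shuffle_temperature:
        temperature = rng.permutation(temperature)
        temp_expect = temperature  # covers follow the shuffled field

    warm = (temp_expect - tmin) / (tmax - tmin)
    base = np.asarray(cfg.cover_concentration, dtype=float)
    slopes = cfg.cover_gradient * np.array(
        [_COVER_WARM_SLOPE[c] for c in COVER_CLASSES]
    )
    cover = np.empty((cfg.n_sites, len(COVER_CLASSES)))
    for i in range(cfg.n_sites):
        alpha = base * np.exp(slopes * (warm[i] - 0.5))
        cover[i] = rng.dirichlet(alpha)

    population = rng.lognormal(
        mean=np.log(cfg.pop_scale) + warm - 0.5, sigma=1.0, size=cfg.n_sites
    )
    elev_mu, elev_sd = cfg.elev_params
    elev_mean = np.abs(
        elev_mu * (0.4 + 1.2 * (1.0 - warm)) + rng.normal(0.0, elev_sd, cfg.n_sites)
    )
    elev_var = np.abs(rng.normal(elev_sd, elev_sd / 3.0, cfg.n_sites))

    env = pd.DataFrame(
        {
            "temperature": temperature,
            **{c: cover[:, k] for k, c in enumerate(COVER_CLASSES)},
            "population": population,
            "elev_mean": elev_mean,
            "elev_sd": elev_var,
            "x": (col_idx + 0.5) * _CELL_KM,
            "y": (rows - 1 - row_idx + 0.5) * _CELL_KM,
        },
        index=pd.Index(
            [f"s{i + 1:04d}" for i in range(cfg.n_sites)], name="site"
        ),
    )
    env.insert(
        len(COVER_CLASSES) + 1,
        "heterogeneity",
        shannon_heterogeneity(env[list(COVER_CLASSES)]),
    )
    return env


def generate_species_pool(
    cfg: SpeciesPoolConfig, landscape: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample categorical traits and thermal niche parameters.

    Returns ``(traits, niches)`` where ``niches`` carries each species'
    thermal optimum, niche breadth and detection baseline — the ground
    truth used by the community generator.
    """
    rng = np.random.default_rng(cfg.seed)
    levels = dict(
        zip(
            TRAIT_COLUMNS,
            (BODY_SIZE_CLASSES, VOLTINISM_CLASSES, OVERWINTERING_STAGES, DIET_CLASSES),
        )
    )
    species = [f"sp{j + 1:03d}" for j in range(cfg.n_species)]
    traits = {}
    for trait, lv in levels.items():
        probs = cfg.trait_level_probs.get(trait)
        if probs is None:
            probs = np.full(len(lv), 1.0 / len(lv))
        traits[trait] = rng.choice(lv, size=cfg.n_species, p=np.asarray(probs))
    trait_table = pd.DataFrame(traits, index=pd.Index(species, name="species"))

    t = landscape["temperature"].to_numpy()
    opt_lo, opt_hi = (
        cfg.optimum_range
        if cfg.optimum_range is not None
        else (float(t.min()), float(t.max()))
    )
    niches = pd.DataFrame(
        {
            "optimum": rng.uniform(opt_lo, opt_hi, cfg.n_species),
            "breadth": rng.uniform(*cfg.niche_breadth_range, cfg.n_species),
            "baseline": np.full(cfg.n_species, cfg.detection_baseline),
        },
        index=trait_table.index,
    )
    return trait_table, niches


def occupancy_probability(
    landscape: pd.DataFrame, niches: pd.DataFrame
) -> pd.DataFrame:
    """Site × species occupancy probabilities of the niche model."""
    t = landscape["temperature"].to_numpy()[:, None]
    opt = niches["optimum"].to_numpy()[None, :]
    br = niches["breadth"].to_numpy()[None, :]
    base = niches["baseline"].to_numpy()[None, :]
    with np.errstate(over="ignore"):
        p = base * np.exp(-((t - opt) ** 2) / (2.0 * br**2))
    return pd.DataFrame(p, index=landscape.index, columns=niches.index)


def generate_communities(
    landscape: pd.DataFrame,
    niches: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli presence/absence draws from the niche occupancy model."""
    p = occupancy_probability(landscape, niches)
    rng = np.random.default_rng(seed)
    occ = (rng.random(p.shape) < p.to_numpy()).astype(np.int8)
    return pd.DataFrame(occ, index=p.index, columns=p.columns)


@dataclass
class SyntheticDataset:
    """Bundle of generated tables plus the generating ground truth."""

    name: str
    community: pd.DataFrame
    traits: pd.DataFrame
    environment: pd.DataFrame
    niches: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        """Write the three tables as CSV and the truth as key=value text."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.community.rename_axis("site").to_csv(out / "community.csv")
        self.traits.rename_axis("species").to_csv(out / "traits.csv")
        self.environment.rename_axis("site").to_csv(out / "environment.csv")
        self.niches.rename_axis("species").to_csv(out / "niches.csv")
        with open(out / "truth.txt", "w") as fh:
            for k, v in self.truth.items():
                fh.write(f"{k}={v}\n")


def _grid_for(n_sites: int) -> tuple[int, int]:
    """Near-square (rows, cols) factorization of n_sites."""
    rows = int(np.sqrt(n_sites))
    while rows > 1 and n_sites % rows != 0:
        rows -= 1
    return rows, n_sites // rows


PRESETS = ("default", "single-driver-temperature", "no-structure")


def make_benchmark_dataset(
    name: str, n_sites: int | None = None, seed: int = 0
) -> SyntheticDataset:
    """Construct one of the named benchmark datasets.

    * ``default`` — latitudinal gradient, cover–temperature confound,
      warm-skewed species pool: richness increases with temperature and
      turnover is driven by both distance and temperature.
    * ``single-driver-temperature`` — temperature spatially shuffled and
      cover flat, so turnover tracks temperature only.
    * ``no-structure`` — constant occupancy probability everywhere:
      spatially unstructured random communities.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; known presets: {PRESETS}")
    n = n_sites if n_sites is not None else {"default": 120}.get(name, 200)
    rows, cols = _grid_for(n)

    if name == "default":
        land_cfg = LandscapeConfig(n_sites=n, grid_shape=(rows, cols), seed=seed)
        land = generate_landscape(land_cfg)
        t = land["temperature"]
        pool_cfg = SpeciesPoolConfig(
            optimum_range=(float(t.min() + 0.55 * (t.max() - t.min())), float(t.max() + 3.0)),
            niche_breadth_range=(2.5, 7.0),
            seed=seed + 1,
        )
        driver = "temperature+geography"
    elif name == "single-driver-temperature":
        land_cfg = LandscapeConfig(
            n_sites=n,
            grid_shape=(rows, cols),
            shuffle_temperature=True,
            cover_gradient=0.0,
            temp_noise_sd=0.5,
            seed=seed,
        )
        land = generate_landscape(land_cfg)
        pool_cfg = SpeciesPoolConfig(
            niche_breadth_range=(1.5, 3.0), detection_baseline=0.85, seed=seed + 1
        )
        driver = "temperature"
    else:  # no-structure
        land_cfg = LandscapeConfig(
            n_sites=n, grid_shape=(rows, cols), cover_gradient=0.0, seed=seed
        )
        land = generate_landscape(land_cfg)
        pool_cfg = SpeciesPoolConfig(
            niche_breadth_range=(1e6, 1e6), detection_baseline=0.35, seed=seed + 1
        )
        driver = "none"

    traits, niches = generate_species_pool(pool_cfg, land)
    community = generate_communities(land, niches, seed=seed + 2)
    truth = {
        "preset": name,
        "turnover_driver": driver,
        "seed": seed,
        "n_sites": n,
        "n_species": pool_cfg.n_species,
        **{f"optimum_{sp}": round(float(o), 6) for sp, o in niches["optimum"].items()},
        **{f"breadth_{sp}": round(float(b), 6) for sp, b in niches["breadth"].items()},
    }
    return SyntheticDataset(
        name=name,
        community=community,
        traits=traits,
        environment=land,
        niches=niches,
        truth=truth,
    )
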