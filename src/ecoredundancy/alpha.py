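"""Per-site (alpha) diversity metrics and predictor screening.

Covers species richness, convex-hull functional richness (FRic)
standardized by the species pool's hull volume, standardized effect
sizes of FRic under a fixed-margin swap null model, Shannon diversity
of land-cover shares, and iterative variance-inflation-factor
screening of environmental predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .trait_space import TraitSpace

__all__ = [
    "NullModelConfig",
    "species_richness",
    "functional_richness",
    "swap_randomize",
    "ses_functional_richness",
    "shannon_heterogeneity",
    "vif_screen",
]


def species_richness(community: pd.DataFrame) -> pd.Series:
    """Row sums of the binary occurrence matrix."""
    vals = community.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("community matrix must be binary")
    return pd.Series(vals.sum(axis=1).astype(int), index=community.index, name="S")


def _hull_volume_or_nan(points: np.ndarray) -> float:
    """Convex hull volume; NaN for too-few or degenerate point sets."""
    m = points.shape[1]
    points = np.unique(points, axis=0)
    if points.shape[0] < m + 1:
        return float("nan")
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return float("nan")


def _site_fric(
    occ: np.ndarray, coords: np.ndarray, pool_volume: float
) -> np.ndarray:
    out = np.full(occ.shape[0], np.nan)
    for i in range(occ.shape[0]):
        v = _hull_volume_or_nan(coords[occ[i]])
        if np.isfinite(v):
            out[i] = v / pool_volume
    return out


def functional_richness(
    community: pd.DataFrame, space: TraitSpace, m_axes: int = 3
) -> pd.Series:
    """Per-site FRic: hull volume of the present species' unique trait
    coordinates in the first ``m_axes`` axes, divided by the pool hull.

    Sites with fewer than ``m_axes + 1`` unique points, or whose points
    are degenerate (span fewer than ``m_axes`` dimensions), get NaN.
    """
    if m_axes > space.coordinates.shape[1]:
        raise ValueError(
            f"m_axes={m_axes} exceeds the {space.coordinates.shape[1]} available axes"
        )
    coords = space.coordinates.reindex(community.columns).to_numpy()[:, :m_axes]
    if np.isnan(coords).any():
        missing = [
            s
            for s in community.columns
            if s not in space.coordinates.index
        ]
        raise KeyError(f"species absent from trait space: {missing[:5]}")
    pool_volume = _hull_volume_or_nan(coords)
    if not np.isfinite(pool_volume) or pool_volume <= 0:
        raise ValueError("species pool hull is degenerate in the requested axes")
    occ = community.to_numpy(dtype=bool)
    return pd.Series(
        _site_fric(occ, coords, pool_volume), index=community.index, name="FRic"
    )


@dataclass
class NullModelConfig:
    """Configuration of the fixed-margin swap null model."""

    n_randomizations: int = 1000
    burn_in: int | None = None  # trial swaps; default 10 × number of presences
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_randomizations < 2:
            raise ValueError("n_randomizations must be at least 2")


try:  # numba speeds the swap chain up by ~two orders of magnitude
    from numba import njit

    @njit(cache=True)
    def _swap_trials_numba(mat, rows, cols):  # pragma: no cover - jitted
        n_trials = rows.shape[0]
        for t in range(n_trials):
            r1, r2 = rows[t, 0], rows[t, 1]
            c1, c2 = cols[t, 0], cols[t, 1]
            if r1 == r2 or c1 == c2:
                continue
            a = mat[r1, c1]
            b = mat[r1, c2]
            c = mat[r2, c1]
            d = mat[r2, c2]
            if a == d and b == c and a != b:
                mat[r1, c1] = b
                mat[r1, c2] = a
                mat[r2, c1] = d
                mat[r2, c2] = c

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _run_swaps(mat: np.ndarray, n_trials: int, rng: np.random.Generator) -> None:
    rows = rng.integers(0, mat.shape[0], size=(n_trials, 2))
    cols = rng.integers(0, mat.shape[1], size=(n_trials, 2))
    if _HAVE_NUMBA:
        _swap_trials_numba(mat, rows, cols)
    else:
        for t in range(n_trials):
            r1, r2 = rows[t]
            c1, c2 = cols[t]
            if r1 == r2 or c1 == c2:
                continue
            a, b = mat[r1, c1], mat[r1, c2]
            c, d = mat[r2, c1], mat[r2, c2]
            if a == d and b == c and a != b:
                mat[r1, c1], mat[r1, c2] = b, a
                mat[r2, c1], mat[r2, c2] = d, c


def swap_randomize(
    community: pd.DataFrame,
    cfg: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One margin-preserving randomization of a binary matrix.

    Repeated random 2×2 checkerboard trial swaps leave every row and
    column sum untouched; the chain is run for ``burn_in`` trials
    (default 10 × the number of presences) from the observed matrix.
    """
    cfg = cfg or NullModelConfig()
    mat = community.to_numpy().astype(np.int8)
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("community matrix must be binary")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.burn_in if cfg.burn_in is not None else max(10 * int(mat.sum()), 100)
    _run_swaps(mat, n_trials, rng)
    return pd.DataFrame(mat, index=community.index, columns=community.columns)


def ses_functional_richness(
    community: pd.DataFrame,
    space: TraitSpace,
    m_axes: int = 3,
    cfg: NullModelConfig | None = None,
) -> pd.DataFrame:
    """Standardized effect size of FRic under the swap null model.

    SES_i = (FRic_obs,i − mean_null,i) / sd_null,i.  Sites whose null
    standard deviation is zero (or with undefined observed FRic) get
    NaN.  Each randomization runs an independent swap chain seeded from
    the master seed.
    """
    cfg = cfg or NullModelConfig()
    obs = functional_richness(community, space, m_axes=m_axes)
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**63 - 1, size=cfg.n_randomizations)

    coords = space.coordinates.reindex(community.columns).to_numpy()[:, :m_axes]
    pool_volume = _hull_volume_or_nan(coords)
    base = community.to_numpy().astype(np.int8)
    n_trials = cfg.burn_in if cfg.burn_in is not None else max(10 * int(base.sum()), 100)

    null_sum = np.zeros(len(community))
    null_sumsq = np.zeros(len(community))
    null_n = np.zeros(len(community))
    for s in seeds:
        rng = np.random.default_rng(int(s))
        mat = base.copy()
        _run_swaps(mat, n_trials, rng)
        fric = _site_fric(mat.astype(bool), coords, pool_volume)
        ok = np.isfinite(fric)
        null_sum[ok] += fric[ok]
        null_sumsq[ok] += fric[ok] ** 2
        null_n[ok] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = null_sum / null_n
        var = null_sumsq / null_n - mean**2
        sd = np.sqrt(np.maximum(var, 0.0))
        ses = (obs.to_numpy() - mean) / sd
    degenerate = (sd <= 1e-12) & np.isfinite(obs.to_numpy())
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} site(s) have zero null SD; SES set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    ses[sd <= 1e-12] = np.nan
    return pd.DataFrame(
        {
            "FRic_obs": obs,
            "null_mean": mean,
            "null_sd": sd,
            "SES_FRic": ses,
        },
        index=community.index,
    )


def shannon_heterogeneity(cover: np.ndarray | pd.Series | pd.DataFrame) -> float | pd.Series:
    """Shannon diversity H = −Σ p ln p of land-cover shares.

    Shares are renormalized to sum to one over the classes with a
    positive share; zero-share classes contribute nothing.  Accepts a
    single vector of shares or a sites × classes frame (returns a
    per-site Series).
    """
    if isinstance(cover, pd.DataFrame):
        return pd.Series(
            [shannon_heterogeneity(row.to_numpy()) for _, row in cover.iterrows()],
            index=cover.index,
            name="heterogeneity",
        )
    p = np.asarray(cover, dtype=float)
    if (p < 0).any():
        raise ValueError("cover fractions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("at least one cover fraction must be positive")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def vif_screen(
    env: pd.DataFrame, predictors: list[str], threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iterative VIF screening (vifstep-style).

    Repeatedly computes VIF_k = 1/(1 − R²_k) from an OLS regression of
    each predictor on all the others and drops the worst offender until
    every VIF is below ``threshold``.  Exact linear dependence shows up
    as an infinite VIF and is dropped first.

    Returns the retained predictor list and a trace table with one row
    per dropped predictor (name, VIF at drop time, step).
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors to screen")
    x = env[predictors].to_numpy(dtype=float)
    if x.shape[0] < len(predictors) + 1:
        raise ValueError("need more sites than predictors")
    retained = list(predictors)
    dropped = []
    step = 0
    while len(retained) >= 2:
        vifs = {}
        xr = env[retained].to_numpy(dtype=float)
        for k, name in enumerate(retained):
            y = xr[:, k]
            others = np.delete(xr, k, axis=1)
            a = np.column_stack([np.ones(len(y)), others])
            coef, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
            resid = y - a @ coef
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            if ss_tot <= 0:
                vifs[name] = np.inf
                continue
            r2 = 1.0 - ss_res / ss_tot
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(vifs, key=lambda n: vifs[n])
        if vifs[worst] < threshold:
            break
        step += 1
        retained.remove(worst)
        dropped.append((worst, vifs[worst], step))
    trace = pd.DataFrame(dropped, columns=["predictor", "vif", "step"])
    return retained, trace
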