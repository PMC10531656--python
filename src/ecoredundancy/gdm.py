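"""Generalized dissimilarity modelling of pairwise β-diversity.

The model regresses observed pairwise dissimilarity d on monotone
I-spline transforms of the between-site predictor differences under a
negative-exponential link:

    d_hat = 1 - exp(-eta),
    eta   = alpha + sum_k sum_b beta_kb |I_kb(x_ki) - I_kb(x_kj)|

with geographic distance entering through I-splines of the distance
value itself.  All coefficients (and the intercept) are non-negative,
which together with the monotone basis guarantees monotone fitted
transforms.  Coefficients are estimated by iteratively reweighted
non-negative least squares on the binomial-type deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform

from .beta import DissimilarityMatrix
from .trait_space import pcoa

__all__ = [
    "ispline_basis",
    "build_site_pairs",
    "GDMFit",
    "fit_gdm",
    "predictor_importance",
    "DeviancePartition",
    "partition_deviance",
    "predict_dissimilarity",
    "rgb_ordination",
]

GEO = "geo_distance"
_EPS = 1e-6


def _ispline_knots(x: np.ndarray) -> np.ndarray:
    """Knot triple (min, median, max) with a degenerate-median guard."""
    lo, mid, hi = float(np.min(x)), float(np.median(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("constant predictor: cannot place I-spline knots")
    if not lo < mid < hi:
        mid = 0.5 * (lo + hi)
    return np.array([lo, mid, hi])


def ispline_basis(x: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """Monotone order-2 I-spline basis with 3 functions.

    Each basis function is non-decreasing, 0 at the minimum knot and 1
    at the maximum knot.  Values outside the knot range are clamped.

    Returns an (n, 3) matrix.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = _ispline_knots(x)
    t0, t1, t2 = knots
    xc = np.clip(x, t0, t2)
    # degree-2 B-splines on an open knot vector; right-tail cumulative
    # sums of the 4 basis functions give monotone 0->1 I-splines
    kv = np.array([t0, t0, t0, t1, t2, t2, t2])
    design = BSpline.design_matrix(xc, kv, 2, extrapolate=False).toarray()
    rev_cum = np.cumsum(design[:, ::-1], axis=1)[:, ::-1]
    return rev_cum[:, 1:4]


def build_site_pairs(
    dissim: DissimilarityMatrix | pd.DataFrame,
    env: pd.DataFrame,
    predictors: list[str],
    coord_cols: tuple[str, str] = ("x", "y"),
) -> pd.DataFrame:
    """Long table of all unordered site pairs for GDM fitting.

    Each row carries the observed dissimilarity, each predictor's value
    at both sites, and the Euclidean geographic distance between the
    sites' planar coordinates.
    """
    mat = dissim.matrix if isinstance(dissim, DissimilarityMatrix) else dissim
    sites = list(mat.index)
    missing = [s for s in sites if s not in env.index]
    if missing:
        raise KeyError(f"sites missing from environment table: {missing[:5]}")
    for col in list(predictors) + list(coord_cols):
        if col not in env.columns:
            raise KeyError(f"environment table lacks column {col!r}")
    sub = env.loc[sites]
    xy = sub[list(coord_cols)].to_numpy(dtype=float)
    geo = squareform(pdist(xy))
    d = mat.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(sites), k=1)
    data = {
        "site_i": [sites[i] for i in iu],
        "site_j": [sites[j] for j in ju],
        "d": d[iu, ju],
        GEO: geo[iu, ju],
    }
    for p in predictors:
        vals = sub[p].to_numpy(dtype=float)
        data[f"{p}_i"] = vals[iu]
        data[f"{p}_j"] = vals[ju]
    out = pd.DataFrame(data)
    return out[np.isfinite(out["d"])].reset_index(drop=True)


@dataclass
class GDMFit:
    """Fitted generalized dissimilarity model."""

    predictors: list[str]  # environmental predictors (GEO handled separately)
    include_geo: bool
    intercept: float
    coefficients: dict  # predictor -> array of 3 non-negative coefficients
    knots: dict  # predictor -> knot triple
    deviance: float
    null_deviance: float
    deviance_explained: float  # percent
    converged: bool
    n_iter: int
    deviance_trace: list = field(default_factory=list, repr=False)

    def transform(self, predictor: str, grid: np.ndarray) -> np.ndarray:
        """Fitted monotone transform f(x) = sum_b beta_b I_b(x) on a grid."""
        basis = ispline_basis(np.asarray(grid, dtype=float), self.knots[predictor])
        return basis @ self.coefficients[predictor]


def _design_matrix(
    pairs: pd.DataFrame,
    predictors: list[str],
    include_geo: bool,
    knots: dict,
    clamp_warn: bool = False,
) -> np.ndarray:
    cols = [np.ones(len(pairs))]
    for p in predictors:
        xi = pairs[f"{p}_i"].to_numpy(dtype=float)
        xj = pairs[f"{p}_j"].to_numpy(dtype=float)
        kt = knots[p]
        if clamp_warn and (
            min(xi.min(), xj.min()) < kt[0] - 1e-12
            or max(xi.max(), xj.max()) > kt[2] + 1e-12
        ):
            warnings.warn(
                f"predictor {p!r} outside training range; values clamped",
                RuntimeWarning,
                stacklevel=3,
            )
        cols.append(np.abs(ispline_basis(xi, kt) - ispline_basis(xj, kt)))
    if include_geo:
        g = pairs[GEO].to_numpy(dtype=float)
        kt = knots[GEO]
        if clamp_warn and (g.min() < kt[0] - 1e-12 or g.max() > kt[2] + 1e-12):
            warnings.warn(
                "geographic distance outside training range; values clamped",
                RuntimeWarning,
                stacklevel=3,
            )
        cols.append(ispline_basis(g, kt))
    return np.column_stack(cols)


def _deviance(d: np.ndarray, mu: np.ndarray) -> float:
    """Binomial-type deviance with 0*log(0) = 0 and mu clamped."""
    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _irls_nnls(
    x: np.ndarray, d: np.ndarray, max_iter: int = 100, rtol: float = 1e-8
) -> tuple[np.ndarray, float, bool, int, list]:
    """Non-negative ML fit of d ~ 1 - exp(-X b) under binomial deviance."""
    mu = np.clip(0.5 * (d + d.mean()), _EPS, 1.0 - _EPS)
    beta = np.zeros(x.shape[1])
    dev = _deviance(d, mu)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = -np.log1p(-mu)
        dmu = 1.0 - mu  # d mu / d eta under the negative-exponential link
        z = eta + (d - mu) / dmu
        w = dmu**2 / np.maximum(mu * (1.0 - mu), _EPS)
        sw = np.sqrt(w)
        beta_new, _ = nnls(sw[:, None] * x, sw * z)
        mu_new = np.clip(-np.expm1(-(x @ beta_new)), _EPS, 1.0 - _EPS)
        dev_new = _deviance(d, mu_new)
        trace.append(dev_new)
        beta, mu = beta_new, mu_new
        if abs(dev - dev_new) <= rtol * max(abs(dev), 1.0):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    return beta, dev, converged, it, trace


def fit_gdm(
    pairs: pd.DataFrame,
    predictors: list[str],
    include_geo: bool = True,
    max_iter: int = 100,
) -> GDMFit:
    """Fit a GDM to a site-pair table.

    ``predictors`` are environmental columns (their ``_i``/``_j`` pair
    values must exist in ``pairs``); geographic distance is added as a
    predictor of its own when ``include_geo``.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 site pairs")
    if not predictors and not include_geo:
        raise ValueError("need at least one predictor")
    d = pairs["d"].to_numpy(dtype=float)
    if not (np.isfinite(d).all() and (d >= 0).all() and (d <= 1).all()):
        raise ValueError("observed dissimilarities must be finite and in [0, 1]")

    knots = {}
    for p in predictors:
        vals = np.concatenate(
            [pairs[f"{p}_i"].to_numpy(dtype=float), pairs[f"{p}_j"].to_numpy(dtype=float)]
        )
        knots[p] = _ispline_knots(vals)
    if include_geo:
        knots[GEO] = _ispline_knots(pairs[GEO].to_numpy(dtype=float))

    x = _design_matrix(pairs, predictors, include_geo, knots)
    beta, dev, converged, n_iter, trace = _irls_nnls(x, d, max_iter=max_iter)
    if not converged:
        raise RuntimeError(
            f"GDM did not converge in {max_iter} iterations; deviance trace: "
            f"{trace[:3]} ... {trace[-3:]}"
        )

    # null model: intercept only, same estimation scheme
    x0 = np.ones((len(d), 1))
    _, null_dev, _, _, _ = _irls_nnls(x0, d, max_iter=max_iter)

    coeffs = {}
    pos = 1
    for p in predictors:
        coeffs[p] = beta[pos : pos + 3].copy()
        pos += 3
    if include_geo:
        coeffs[GEO] = beta[pos : pos + 3].copy()

    dev_expl = 0.0 if null_dev <= 1e-12 else 100.0 * (1.0 - dev / null_dev)
    return GDMFit(
        predictors=list(predictors),
        include_geo=include_geo,
        intercept=float(beta[0]),
        coefficients=coeffs,
        knots=knots,
        deviance=dev,
        null_deviance=null_dev,
        deviance_explained=float(dev_expl),
        converged=converged,
        n_iter=n_iter,
        deviance_trace=trace,
    )


def predictor_importance(fit: GDMFit) -> pd.DataFrame:
    """Per-predictor coefficient sums and normalized shares."""
    names = list(fit.coefficients)
    sums = np.array([fit.coefficients[p].sum() for p in names])
    total = sums.sum()
    share = sums / total if total > 0 else np.zeros_like(sums)
    return pd.DataFrame(
        {"predictor": names, "importance": sums, "share": share}
    ).set_index("predictor")


@dataclass
class DeviancePartition:
    """Deviance explained split into environment / geography components."""

    full: float
    env_only: float
    geo_only: float

    @property
    def unique_env(self) -> float:
        return self.full - self.geo_only

    @property
    def unique_geo(self) -> float:
        return self.full - self.env_only

    @property
    def shared(self) -> float:
        return self.env_only + self.geo_only - self.full

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [
                    "full",
                    "env_only",
                    "geo_only",
                    "unique_env",
                    "unique_geo",
                    "shared",
                ],
                "deviance_explained": [
                    self.full,
                    self.env_only,
                    self.geo_only,
                    self.unique_env,
                    self.unique_geo,
                    self.shared,
                ],
            }
        ).set_index("component")


def partition_deviance(pairs: pd.DataFrame, predictors: list[str]) -> DeviancePartition:
    """Fit full, environment-only and geography-only models on the same
    pair set and partition the explained deviance."""
    full = fit_gdm(pairs, predictors, include_geo=True)
    env_only = fit_gdm(pairs, predictors, include_geo=False)
    geo_only = fit_gdm(pairs, [], include_geo=True)
    return DeviancePartition(
        full=full.deviance_explained,
        env_only=env_only.deviance_explained,
        geo_only=geo_only.deviance_explained,
    )


def predict_dissimilarity(fit: GDMFit, pairs: pd.DataFrame) -> np.ndarray:
    """Predicted dissimilarities d_hat = 1 - exp(-eta) for a pair table.

    Predictor values outside the training range are clamped to the
    training knots with a warning.
    """
    for p in fit.predictors:
        if f"{p}_i" not in pairs.columns or f"{p}_j" not in pairs.columns:
            raise KeyError(f"pair table lacks predictor columns for {p!r}")
    if fit.include_geo and GEO not in pairs.columns:
        raise KeyError(f"pair table lacks column {GEO!r}")
    x = _design_matrix(pairs, fit.predictors, fit.include_geo, fit.knots, clamp_warn=True)
    beta = np.concatenate(
        [[fit.intercept]]
        + [fit.coefficients[p] for p in fit.predictors]
        + ([fit.coefficients[GEO]] if fit.include_geo else [])
    )
    return -np.expm1(-(x @ beta))


def predicted_matrix(fit: GDMFit, pairs: pd.DataFrame, sites: list) -> pd.DataFrame:
    """Square site × site matrix of predicted dissimilarities."""
    pred = predict_dissimilarity(fit, pairs)
    idx = {s: i for i, s in enumerate(sites)}
    m = np.zeros((len(sites), len(sites)))
    for (si, sj), p in zip(pairs[["site_i", "site_j"]].to_numpy(), pred):
        i, j = idx[si], idx[sj]
        m[i, j] = m[j, i] = p
    return pd.DataFrame(m, index=sites, columns=sites)


def rgb_ordination(predicted: pd.DataFrame) -> pd.DataFrame:
    """PCoA of a predicted dissimilarity matrix mapped to RGB channels.

    The first three ordination axes are min-max scaled to [0, 1] and
    reported as R, G, B; a constant axis (or a missing one, when fewer
    than three positive eigenvalues exist) maps to 0.5.
    """
    space = pcoa(predicted, correction="none")
    coords = space.full_coordinates.to_numpy()
    n_axes = coords.shape[1]
    if n_axes < 3:
        warnings.warn(
            f"only {n_axes} positive ordination axes; remaining channels set to 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
    out = {}
    for ch, name in enumerate(["R", "G", "B"]):
        if ch < n_axes:
            axis = coords[:, ch]
            rng = axis.max() - axis.min()
            out[name] = (
                np.full(len(axis), 0.5) if rng <= 1e-12 else (axis - axis.min()) / rng
            )
            out[f"axis_{ch + 1}"] = axis
        else:
            out[name] = np.full(coords.shape[0], 0.5)
            out[f"axis_{ch + 1}"] = np.zeros(coords.shape[0])
    cols = ["axis_1", "axis_2", "axis_3", "R", "G", "B"]
    return pd.DataFrame(out, index=predicted.index)[cols]
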