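"""Penalized smooth additive models (Gaussian family).

Each univariate term uses a small quadratic B-spline basis (three
effective functions, knots at the predictor's min/median/max) with a
second-derivative roughness penalty; an optional bivariate spatial
term uses a low-rank thin-plate-style radial basis over the site
coordinates.  Smoothing parameters are chosen by generalized
cross-validation (coordinate descent over a log-spaced grid).
Deviance explained is 100 * (1 - RSS_model / RSS_null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SmoothModelSpec",
    "SmoothModelFit",
    "fit_smooth_model",
    "spatial_only_model",
    "relate_metrics",
]

log = logging.getLogger(__name__)

_LAMBDA_GRID = np.logspace(-6, 8, 15)
_N_SPATIAL_KNOTS = 30


class _UnivariateTerm:
    """Quadratic B-spline smooth of one predictor (3 basis functions)."""

    def __init__(self, name: str, x: np.ndarray):
        self.name = name
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError(f"predictor {self.name!r} is constant")
        mid = float(np.median(x))
        if not lo < mid < hi:
            mid = 0.5 * (lo + hi)
        self.knots = np.array([lo, lo, lo, mid, hi, hi, hi])
        raw = self._raw(x)
        self.center = raw.mean(axis=0)
        self.penalty = self._second_derivative_gram()

    def _raw(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        full = BSpline.design_matrix(xc, self.knots, 2, extrapolate=False).toarray()
        return full[:, 1:]  # drop one function: intercept is modelled separately

    def basis(self, x: np.ndarray) -> np.ndarray:
        return self._raw(x) - self.center

    def _second_derivative_gram(self) -> np.ndarray:
        # f'' of a quadratic spline is piecewise constant on the two
        # inter-knot intervals, so the Gram integral is exact from
        # midpoint evaluations
        t = self.knots
        breaks = np.array([t[0], t[3], t[-1]])
        mids = 0.5 * (breaks[:-1] + breaks[1:])
        lengths = np.diff(breaks)
        n_basis = len(t) - 3
        d2 = np.zeros((len(mids), n_basis))
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            d2[:, j] = BSpline(t, c, 2)(mids, nu=2)
        d2 = d2[:, 1:]
        return (d2 * lengths[:, None]).T @ d2

    @property
    def n_cols(self) -> int:
        return len(self.center)

    def grid(self, n: int = 100) -> np.ndarray:
        return np.linspace(self.knots[0], self.knots[-1], n)


class _SpatialTerm:
    """Low-rank radial-basis smooth of planar coordinates."""

    name = "spatial"

    def __init__(self, xy: np.ndarray, n_knots: int = _N_SPATIAL_KNOTS):
        xy = np.asarray(xy, dtype=float)
        self.lo = xy.min(axis=0)
        scale = xy.max(axis=0) - self.lo
        self.scale = np.where(scale > 0, scale, 1.0)
        u = self._unit(xy)
        uniq = np.unique(u, axis=0)
        if len(uniq) <= n_knots:
            self.knots = uniq
        else:  # deterministic spread: evenly spaced ranks of a lexicographic sort
            order = np.lexsort((uniq[:, 1], uniq[:, 0]))
            pick = np.linspace(0, len(uniq) - 1, n_knots).round().astype(int)
            self.knots = uniq[order[pick]]
        raw = self._raw(u)
        self.center = raw.mean(axis=0)
        # ridge on the radial coefficients only; the planar (linear)
        # part is left unpenalized
        pen = np.zeros((raw.shape[1], raw.shape[1]))
        pen[2:, 2:] = np.eye(raw.shape[1] - 2)
        self.penalty = pen

    def _unit(self, xy: np.ndarray) -> np.ndarray:
        return (np.asarray(xy, dtype=float) - self.lo) / self.scale

    def _raw(self, u: np.ndarray) -> np.ndarray:
        diff = u[:, None, :] - self.knots[None, :, :]
        r = np.sqrt((diff**2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(r > 0, r**2 * np.log(r), 0.0)
        return np.column_stack([u, phi])

    def basis(self, xy: np.ndarray) -> np.ndarray:
        return self._raw(self._unit(xy)) - self.center

    @property
    def n_cols(self) -> int:
        return len(self.center)


@dataclass
class SmoothModelSpec:
    """What to fit: response, smooth predictors, optional spatial term."""

    response: str
    predictors: list[str] = field(default_factory=list)
    spatial: bool = False
    coord_cols: tuple[str, str] = ("x", "y")
    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be at least 3")
        if not self.predictors and not self.spatial:
            raise ValueError("need at least one predictor or the spatial term")


@dataclass
class SmoothModelFit:
    """Fitted penalized additive model."""

    spec: SmoothModelSpec
    intercept: float
    term_names: list[str]
    coefficients: dict
    lambdas: dict
    fitted: pd.Series
    residuals: pd.Series
    deviance_explained: float  # percent
    edf: float
    gcv: float
    partial_effects: dict  # term name -> DataFrame(grid columns, effect)
    n_dropped: int


def _assemble(terms: list) -> tuple[np.ndarray, list[np.ndarray], list[slice]]:
    blocks = []
    slices = []
    pos = 1
    for t, xdata in terms:
        b = t.basis(xdata)
        blocks.append(b)
        slices.append(slice(pos, pos + b.shape[1]))
        pos += b.shape[1]
    n = blocks[0].shape[0]
    x = np.column_stack([np.ones(n)] + blocks)
    return x, blocks, slices


def _penalized_fit(
    x: np.ndarray, y: np.ndarray, penalties: list[np.ndarray], slices: list[slice],
    lambdas: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    p = x.shape[1]
    s = np.zeros((p, p))
    for pen, sl, lam in zip(penalties, slices, lambdas):
        s[sl, sl] += lam * pen
    xtx = x.T @ x
    a = xtx + s + 1e-10 * np.eye(p)
    try:
        beta = np.linalg.solve(a, x.T @ y)
        edf = float(np.trace(np.linalg.solve(a, xtx)))
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(a, x.T @ y, rcond=None)
        edf = float(np.trace(np.linalg.lstsq(a, xtx, rcond=None)[0]))
    resid = y - x @ beta
    rss = float(resid @ resid)
    return beta, rss, edf


def _gcv_score(n: int, rss: float, edf: float) -> float:
    denom = max(n - edf, 1e-8)
    return n * rss / denom**2


def _select_lambdas(
    x: np.ndarray, y: np.ndarray, penalties: list, slices: list, n_terms: int
) -> np.ndarray:
    n = len(y)
    lambdas = np.full(n_terms, 1.0)
    best = np.inf
    for _ in range(3):  # coordinate-descent passes
        improved = False
        for t in range(n_terms):
            for lam in _LAMBDA_GRID:
                trial = lambdas.copy()
                trial[t] = lam
                _, rss, edf = _penalized_fit(x, y, penalties, slices, trial)
                score = _gcv_score(n, rss, edf)
                if score < best - 1e-12:
                    best = score
                    lambdas = trial
                    improved = True
        if not improved:
            break
    return lambdas


def fit_smooth_model(metrics: pd.DataFrame, spec: SmoothModelSpec) -> SmoothModelFit:
    """Fit the penalized additive model described by ``spec``.

    Rows with missing values in the response or any predictor are
    dropped (their count is logged and reported on the fit).
    """
    cols = [spec.response] + list(spec.predictors)
    if spec.spatial:
        cols += list(spec.coord_cols)
    missing = [c for c in cols if c not in metrics.columns]
    if missing:
        raise KeyError(f"metrics table lacks columns: {missing}")
    data = metrics[cols].apply(pd.to_numeric, errors="coerce")
    keep = data.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d incomplete rows of %d", n_dropped, len(data))
    data = data[keep]
    y = data[spec.response].to_numpy(dtype=float)

    terms = []
    for p in spec.predictors:
        xv = data[p].to_numpy(dtype=float)
        terms.append((_UnivariateTerm(p, xv), xv))
    if spec.spatial:
        xy = data[list(spec.coord_cols)].to_numpy(dtype=float)
        # keep the total basis well under the row count
        budget = (len(data) - 2 - 3 * len(spec.predictors)) // 2
        n_knots = int(np.clip(budget, 4, _N_SPATIAL_KNOTS))
        terms.append((_SpatialTerm(xy, n_knots=n_knots), xy))

    x, blocks, slices = _assemble(terms)
    if x.shape[0] <= x.shape[1]:
        raise ValueError(
            f"{x.shape[0]} rows cannot support a basis of dimension {x.shape[1]}"
        )
    penalties = [t.penalty for t, _ in terms]
    lambdas = _select_lambdas(x, y, penalties, slices, len(terms))
    beta, rss, edf = _penalized_fit(x, y, penalties, slices, lambdas)
    fitted = x @ beta
    rss_null = float(((y - y.mean()) ** 2).sum())
    dev_expl = 0.0 if rss_null <= 1e-12 else 100.0 * (1.0 - rss / rss_null)

    names = [t.name for t, _ in terms]
    coefs = {name: beta[sl].copy() for name, sl in zip(names, slices)}
    partials = {}
    for (t, _), name, sl in zip(terms, names, slices):
        if isinstance(t, _UnivariateTerm):
            grid = t.grid()
            eff = t.basis(grid) @ beta[sl]
            partials[name] = pd.DataFrame({name: grid, "effect": eff})
        else:
            partials[name] = pd.DataFrame(
                {"x": terms[-1][1][:, 0], "y": terms[-1][1][:, 1],
                 "effect": t.basis(terms[-1][1]) @ beta[sl]}
            )
    idx = data.index
    return SmoothModelFit(
        spec=spec,
        intercept=float(beta[0]),
        term_names=names,
        coefficients=coefs,
        lambdas=dict(zip(names, lambdas)),
        fitted=pd.Series(fitted, index=idx, name="fitted"),
        residuals=pd.Series(y - fitted, index=idx, name="residuals"),
        deviance_explained=float(max(dev_expl, 0.0)),
        edf=edf,
        gcv=_gcv_score(len(y), rss, edf),
        partial_effects=partials,
        n_dropped=n_dropped,
    )


def spatial_only_model(
    metrics: pd.DataFrame,
    response: str,
    coord_cols: tuple[str, str] = ("x", "y"),
) -> SmoothModelFit:
    """Additive fit with only the bivariate spatial smooth."""
    spec = SmoothModelSpec(
        response=response, predictors=[], spatial=True, coord_cols=coord_cols
    )
    return fit_smooth_model(metrics, spec)


def relate_metrics(
    metrics: pd.DataFrame,
    pair: tuple[str, str],
    spatial: bool = False,
    coord_cols: tuple[str, str] = ("x", "y"),
) -> SmoothModelFit:
    """Univariate smooth of one diversity metric on another.

    ``pair`` is (x metric, y metric): y is modelled as a smooth
    function of x, optionally with the spatial term added.
    """
    x_name, y_name = pair
    spec = SmoothModelSpec(
        response=y_name, predictors=[x_name], spatial=spatial, coord_cols=coord_cols
    )
    return fit_smooth_model(metrics, spec)
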