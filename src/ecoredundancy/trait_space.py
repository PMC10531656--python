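"""Trait binning, Gower distances and principal-coordinate trait space.

Species are described by four categorical traits (body-size class,
voltinism class, overwintering stage, diet breadth).  Continuous wing
span and voltinism are binned into the categorical classes first; the
Gower distance between two all-categorical trait vectors is then the
proportion of mismatching traits.  A PCoA embedding of the distance
matrix provides the Euclidean coordinates used by the convex-hull
functional-richness and functional β-diversity computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BODY_SIZE_CLASSES",
    "VOLTINISM_CLASSES",
    "OVERWINTERING_STAGES",
    "DIET_CLASSES",
    "TRAIT_COLUMNS",
    "TraitSpace",
    "bin_continuous_traits",
    "gower_distance",
    "pcoa",
]

BODY_SIZE_CLASSES = ("20-30", "31-40", "41-50", "51-60", ">60")
VOLTINISM_CLASSES = ("1", "2", "3", "4", "5")
OVERWINTERING_STAGES = ("egg", "larvae", "pupae", "adult")
DIET_CLASSES = ("monophagous", "broad oligophagous", "polyphagous")

#: canonical column order of a categorical trait table
TRAIT_COLUMNS = ("body_size_class", "voltinism_class", "overwintering_stage", "diet")

RAW_TRAIT_COLUMNS = ("wing_span", "voltinism", "overwintering_stage", "diet")

# inclusive integer edges of the wing-span classes
_BODY_SIZE_EDGES = ((20, 30), (31, 40), (41, 50), (51, 60))


class TraitValueError(ValueError):
    """A trait value is missing or outside its allowed range/level set."""


def _body_size_class(wing_span: float, species: str) -> str:
    """Map a continuous wing span (mm) to its class label.

    Values are rounded to the nearest integer first so that the gaps
    between the integer-edged classes (e.g. 30–31) are closed.
    """
    if not np.isfinite(wing_span):
        raise TraitValueError(f"species {species!r}: wing_span is missing or non-finite")
    w = int(np.floor(float(wing_span) + 0.5))  # round half up, not half to even
    if w < 20:
        raise TraitValueError(
            f"species {species!r}: wing span {wing_span} mm is below the smallest class (20-30)"
        )
    for (lo, hi), label in zip(_BODY_SIZE_EDGES, BODY_SIZE_CLASSES):
        if lo <= w <= hi:
            return label
    return BODY_SIZE_CLASSES[-1]  # > 60


def _voltinism_class(voltinism: float, species: str) -> str:
    if not np.isfinite(voltinism):
        raise TraitValueError(f"species {species!r}: voltinism is missing or non-finite")
    v = int(np.floor(float(voltinism) + 0.5))  # round half up
    return VOLTINISM_CLASSES[min(max(v, 1), 5) - 1]


def bin_continuous_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Bin a raw trait table into the four categorical traits.

    Parameters
    ----------
    raw
        Indexed by species id, with columns ``wing_span`` (mm,
        continuous), ``voltinism`` (generations/yr, continuous),
        ``overwintering_stage`` and ``diet`` (categorical).

    Returns
    -------
    DataFrame indexed by species with columns :data:`TRAIT_COLUMNS`.
    """
    missing = [c for c in RAW_TRAIT_COLUMNS if c not in raw.columns]
    if missing:
        raise TraitValueError(f"raw trait table lacks columns: {missing}")
    out = {}
    for sp, row in raw.iterrows():
        stage = row["overwintering_stage"]
        diet = row["diet"]
        if stage not in OVERWINTERING_STAGES:
            raise TraitValueError(f"species {sp!r}: unknown overwintering stage {stage!r}")
        if diet not in DIET_CLASSES:
            raise TraitValueError(f"species {sp!r}: unknown diet class {diet!r}")
        out[sp] = (
            _body_size_class(row["wing_span"], str(sp)),
            _voltinism_class(row["voltinism"], str(sp)),
            stage,
            diet,
        )
    return pd.DataFrame.from_dict(out, orient="index", columns=list(TRAIT_COLUMNS))


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Check a categorical trait table for completeness and known levels."""
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise TraitValueError(f"trait table lacks columns: {missing}")
    levels = dict(
        zip(
            TRAIT_COLUMNS,
            (BODY_SIZE_CLASSES, VOLTINISM_CLASSES, OVERWINTERING_STAGES, DIET_CLASSES),
        )
    )
    out = traits[list(TRAIT_COLUMNS)].copy()
    for col, allowed in levels.items():
        vals = out[col]
        if vals.isna().any():
            sp = out.index[vals.isna()][0]
            raise TraitValueError(f"species {sp!r}: missing value for trait {col!r}")
        vals = vals.astype(str)
        bad = ~vals.isin(allowed)
        if bad.any():
            sp = out.index[bad][0]
            raise TraitValueError(
                f"species {sp!r}: value {vals[bad].iloc[0]!r} not a level of {col!r}"
            )
        out[col] = vals
    return out


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Gower distance matrix for an all-categorical trait table.

    With four categorical traits this reduces to the proportion of
    mismatching traits, so every distance lies in {0, .25, .5, .75, 1}.
    """
    traits = validate_trait_table(traits)
    codes = np.column_stack(
        [pd.factorize(traits[c].astype(str))[0] for c in TRAIT_COLUMNS]
    ).astype(float)
    d = squareform(pdist(codes, metric="hamming"))
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


@dataclass
class TraitSpace:
    """PCoA embedding of a species distance matrix.

    ``coordinates`` holds the first ``m`` requested axes;
    ``full_coordinates`` all positive-eigenvalue axes (used for the
    distance round-trip guarantee).
    """

    species: list
    gower: pd.DataFrame
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction_applied: str = "none"
    full_coordinates: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _double_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _cailliez_constant(d: np.ndarray) -> float:
    # largest real eigenvalue of the companion system of the corrected
    # Gram problem; adding it to every off-diagonal distance makes the
    # matrix Euclidean
    n = d.shape[0]
    delta1 = _double_center(d)
    a2 = -0.5 * d
    row = a2.mean(axis=1, keepdims=True)
    col = a2.mean(axis=0, keepdims=True)
    delta2 = a2 - row - col + a2.mean()
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    real = ev.real[np.abs(ev.imag) < 1e-8]
    return float(max(real.max(), 0.0))


def pcoa(
    dist: pd.DataFrame | np.ndarray,
    m_axes: int | None = None,
    correction: str = "auto",
    *,
    neg_tol: float = 1e-8,
) -> TraitSpace:
    """Principal coordinates analysis of a symmetric distance matrix.

    Parameters
    ----------
    dist
        Symmetric distance matrix with zero diagonal.
    m_axes
        Number of leading axes to expose as ``coordinates``
        (default: all positive-eigenvalue axes).
    correction
        ``"none"``, ``"lingoes"``, ``"cailliez"`` or ``"auto"``
        (Cailliez when the most negative eigenvalue exceeds ``neg_tol``
        in magnitude).

    Pairwise Euclidean distances over all positive-eigenvalue axes of
    the result reproduce the (corrected) input distances to within
    numerical tolerance.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")

    if correction not in ("none", "lingoes", "cailliez", "auto"):
        raise ValueError(f"unknown correction {correction!r}")

    applied = "none"
    g = _double_center(d)
    evals = np.linalg.eigvalsh(g)
    if correction != "none" and evals.min() < -neg_tol:
        if correction in ("cailliez", "auto"):
            c = _cailliez_constant(d)
            d = d + c
            np.fill_diagonal(d, 0.0)
            applied = "cailliez"
        else:  # lingoes: add constant to squared distances
            c = -float(evals.min())
            d2 = d**2 + 2.0 * c
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(d2)
            applied = "lingoes"
        g = _double_center(d)

    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    pos = evals > max(neg_tol, neg_tol * abs(evals[0]) if evals.size else neg_tol)
    n_pos = int(pos.sum())
    coords_full = evecs[:, pos] * np.sqrt(evals[pos])

    if m_axes is None:
        m_axes = n_pos
    if m_axes > n_pos:
        raise ValueError(
            f"m_axes={m_axes} exceeds the number of positive-eigenvalue axes ({n_pos})"
        )
    full = pd.DataFrame(
        coords_full, index=ids, columns=[f"pcoa_{i + 1}" for i in range(n_pos)]
    )
    return TraitSpace(
        species=ids,
        gower=pd.DataFrame(d, index=ids, columns=ids),
        coordinates=full.iloc[:, :m_axes].copy(),
        eigenvalues=evals,
        correction_applied=applied,
        full_coordinates=full,
    )


def build_trait_space(
    traits: pd.DataFrame, m_axes: int = 3, correction: str = "auto"
) -> TraitSpace:
    """Convenience: Gower distances then PCoA on a categorical trait table."""
    g = gower_distance(traits)
    return pcoa(g, m_axes=m_axes, correction=correction)
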