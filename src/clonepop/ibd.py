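"""Isolation by distance: linearized FST against geographic distance.

Differentiation is linearized as ``FST / (1 - FST)`` and regressed on
pairwise geographic distance (km); significance comes from a Mantel
permutation test (simultaneous row/column permutation) and,
separately, from the OLS F test — both are reported because either
convention appears in the literature.  Over-water distances should be
supplied as a labeled matrix; great-circle (haversine) distance is the
fallback when only coordinates are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .differentiation import FstResult

__all__ = [
    "EARTH_RADIUS_KM",
    "linearize_fst",
    "haversine_km",
    "distance_matrix_from_coords",
    "mantel_test",
    "ibd_analysis",
    "IbdResult",
]

EARTH_RADIUS_KM = 6371.0


def linearize_fst(theta: float | np.ndarray) -> float | np.ndarray:
    """Rousset's linearization theta / (1 - theta); monotone for theta < 1.

    Negative estimates pass through (flagged), yielding slightly
    negative linearized values rather than silently truncating.
    """
    arr = np.asarray(theta, dtype=float)
    if np.any(arr >= 1.0):
        raise ValueError("linearization undefined for theta >= 1")
    if np.any(arr < 0.0):
        warnings.warn("negative theta passed through linearization", stacklevel=2)
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(theta) else out


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points in degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def distance_matrix_from_coords(coords: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Pairwise haversine km matrix from {label: (lat, lon)}."""
    labels = list(coords)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(*coords[labels[i]], *coords[labels[j]])
    return pd.DataFrame(d, index=labels, columns=labels)


def _offdiag(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def mantel_test(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper-triangle vectors; the
    null distribution permutes rows and columns of one matrix
    simultaneously.  One-sided p for positive association with the
    add-one convention.
    """
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        if list(X.index) != list(Y.index):
            Y = Y.loc[X.index, X.index]
        X, Y = X.to_numpy(float), Y.to_numpy(float)
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    if X.shape != (n, n) or Y.shape != (n, n):
        raise ValueError("matrices must be square and of equal size")
    x, y = _offdiag(X), _offdiag(Y)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _offdiag(Y[np.ix_(perm, perm)])
        if np.corrcoef(x, yp)[0, 1] >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)


@dataclass
class IbdResult:
    pairs: list[tuple[str, str]]
    x_km: np.ndarray
    y_linfst: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    ols_p: float
    mantel_r: float
    mantel_p: float
    n_perm: int


def ibd_analysis(
    fst_result: FstResult,
    dist_matrix: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> IbdResult:
    """Regress linearized FST on geographic distance across all pairs."""
    labels = [l for l in fst_result.labels if l in dist_matrix.index]
    if len(labels) < 4:
        raise ValueError("need at least 4 populations shared by both matrices")
    order = [fst_result.labels.index(l) for l in labels]
    theta = fst_result.theta[np.ix_(order, order)]
    lin = np.where(np.isnan(theta), np.nan, theta / (1.0 - theta))
    geo = dist_matrix.loc[labels, labels].to_numpy(float)
    iu = np.triu_indices(len(labels), k=1)
    x = geo[iu]
    y = lin[iu]
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    res = sps.linregress(x, y)
    np.fill_diagonal(lin, 0.0)
    mantel_r, mantel_p = mantel_test(geo, lin, n_perm=n_perm, seed=seed)
    return IbdResult(
        pairs=pairs,
        x_km=x,
        y_linfst=y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ols_p=float(res.pvalue),
        mantel_r=mantel_r,
        mantel_p=mantel_p,
        n_perm=n_perm,
    )
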