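"""Ordinary kriging on scattered 2D data.

An exponential variogram is fitted to the empirical semivariogram by
weighted least squares (weights = pair counts per lag bin); the nugget is
fixed at 0 so the predictor interpolates exactly at data locations.
Large data sets use a moving-neighborhood solve (k nearest data points
per query); a singular system falls back to inverse-distance weighting
with a logged warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class ExponentialVariogram:
    """gamma(h) = sill * (1 - exp(-3 h / range)); nugget 0."""

    sill: float
    range_: float

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return self.sill * (1.0 - np.exp(-3.0 * np.asarray(h) / self.range_))


def fit_variogram(coords: np.ndarray, values: np.ndarray, n_bins: int = 15,
                  max_pairs: int = 200_000, rng=None) -> ExponentialVariogram:
    """Fit an exponential model to the empirical semivariogram."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    rng = np.random.default_rng(rng)
    if n * (n - 1) // 2 > max_pairs:
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        keep = i != j
        i, j = i[keep], j[keep]
    else:
        i, j = np.triu_indices(n, k=1)
    d = np.hypot(*(coords[i] - coords[j]).T)
    sv = 0.5 * (values[i] - values[j]) ** 2
    max_lag = d.max()
    if max_lag <= 0:
        return ExponentialVariogram(max(values.var(), 1e-12), 1.0)
    edges = np.linspace(0, max_lag / 2, n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sv, minlength=n_bins)
    ok = counts > 0
    lags = 0.5 * (edges[:-1] + edges[1:])[ok]
    gammas = sums[ok] / counts[ok]
    weights = counts[ok].astype(float)

    var = values.var()
    if var < 1e-14 or gammas.max() < 1e-14 or ok.sum() < 3:
        return ExponentialVariogram(max(var, 1e-12), max_lag / 3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda h, s, r: s * (1.0 - np.exp(-3.0 * h / r)),
                lags, gammas, p0=(var, max_lag / 4),
                sigma=1.0 / np.sqrt(weights),
                bounds=([1e-12, 1e-6], [np.inf, np.inf]), maxfev=5000)
        return ExponentialVariogram(float(popt[0]), float(popt[1]))
    except RuntimeError:
        return ExponentialVariogram(var, max_lag / 3)


def _solve_ok(gamma_mat: np.ndarray, gamma_vec: np.ndarray) -> np.ndarray:
    """Solve the ordinary-kriging system; returns weights (n,) or raises."""
    n = gamma_mat.shape[0]
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_mat
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = gamma_vec
    b[n] = 1.0
    w = np.linalg.solve(a, b)
    return w[:n]


def krige(coords: np.ndarray, values: np.ndarray, query: np.ndarray,
          variogram: ExponentialVariogram | None = None,
          n_neighbors: int = 24, exact_radius: float = 1e-9,
          return_weights: bool = False):
    """Ordinary-kriging prediction at `query` (m, 2) locations.

    With <= `n_neighbors` data points the full system is solved once;
    otherwise each query uses its k nearest data points.  Weights always
    sum to 1; a query coincident with a data point returns that value.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).reshape(-1)
    query = np.asarray(query, dtype=float).reshape(-1, 2)
    n = len(values)
    if n < 2:
        raise ValueError("kriging needs at least 2 data points")
    if variogram is None:
        variogram = fit_variogram(coords, values)

    # constant field: every weight vector summing to 1 reproduces it
    if np.ptp(values) < 1e-12 or variogram.sill < 1e-12:
        out = np.full(len(query), values.mean())
        if return_weights:
            return out, np.full((len(query), n), 1.0 / n), np.arange(n)
        return out

    tree = cKDTree(coords)
    if n <= n_neighbors:
        idx = np.broadcast_to(np.arange(n), (len(query), n))
    else:
        _, idx = tree.query(query, k=n_neighbors)
    k = idx.shape[1]
    preds = np.empty(len(query))
    weights_out = np.empty((len(query), k)) if return_weights else None
    fell_back = False
    for qi in range(len(query)):
        sel = idx[qi]
        pts = coords[sel]
        d_pq = np.hypot(*(pts - query[qi]).T)
        near = d_pq < exact_radius
        if near.any():
            preds[qi] = values[sel[np.argmin(d_pq)]]
            if return_weights:
                w = np.zeros(k)
                w[np.argmin(d_pq)] = 1.0
                weights_out[qi] = w
            continue
        dmat = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                        pts[:, None, 1] - pts[None, :, 1])
        try:
            w = _solve_ok(variogram(dmat), variogram(d_pq))
        except np.linalg.LinAlgError:
            fell_back = True
            w = 1.0 / np.maximum(d_pq, 1e-12) ** 2
            w /= w.sum()
        preds[qi] = w @ values[sel]
        if return_weights:
            weights_out[qi] = w
    if fell_back:
        warnings.warn("singular kriging system: fell back to "
                      "inverse-distance weighting", RuntimeWarning)
    if return_weights:
        return preds, weights_out, idx
    return preds
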