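"""Spatially autocorrelated error fields and spatial diagnostics.

The site-level ageing error is a zero-mean Gaussian random field over the
sampling sites.  Its second-order structure is specified geostatistically by
a covariogram with nugget, sill and range:

    C(0) = sill,    C(h) = (sill - nugget) * rho(h / range)   for h > 0,

equivalently a semivariogram gamma(h) = nugget + (sill - nugget) *
(1 - rho(h / range)).  Supported correlation families: ``exponential``
(rho(u) = exp(-u)), ``gaussian`` (exp(-u^2)) and ``spherical``
(1 - 1.5u + 0.5u^3 for u < 1, else 0).  Fields are drawn exactly via a
Cholesky factor of the covariance over the site coordinates, which is cheap
at survey scale (a few hundred sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

_FAMILIES = ("exponential", "gaussian", "spherical")


@dataclass(frozen=True)
class SpatialErrorModel:
    """Covariogram for the site-level ageing-error field.

    Parameters
    ----------
    family
        Correlation family (exponential / gaussian / spherical).
    nugget
        Micro-scale (spatially independent) variance, years^2.
    sill
        Total variance of the field, years^2; ``sill >= nugget``.
    range_
        Correlation range in the units of the site coordinates (degrees
        here; the field is simulated on planar coordinates).
    """

    family: str = "exponential"
    nugget: float = 0.05
    sill: float = 0.25
    range_: float = 1.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown covariogram family {self.family!r}; use one of {_FAMILIES}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def correlation(self, h: np.ndarray) -> np.ndarray:
        """Correlation rho(h/range) of the structured component at lag h."""
        u = np.asarray(h, dtype=float) / self.range_
        if self.family == "exponential":
            return np.exp(-u)
        if self.family == "gaussian":
            return np.exp(-(u**2))
        rho = 1.0 - 1.5 * u + 0.5 * u**3
        return np.where(u < 1.0, rho, 0.0)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Covariance at lag h; the nugget contributes only at h == 0."""
        h = np.asarray(h, dtype=float)
        partial = self.sill - self.nugget
        cov = partial * self.correlation(h)
        return np.where(h == 0.0, self.sill, cov)

    def semivariogram(self, h: np.ndarray) -> np.ndarray:
        """Model semivariogram gamma(h) = sill - C(h) for h > 0."""
        h = np.asarray(h, dtype=float)
        partial = self.sill - self.nugget
        return np.where(h == 0.0, 0.0, self.nugget + partial * (1.0 - self.correlation(h)))


def covariance_matrix(coords: np.ndarray, model: SpatialErrorModel) -> np.ndarray:
    """Covariance matrix of the field over the given (n, 2) coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = cdist(coords, coords)
    cov = (model.sill - model.nugget) * model.correlation(d)
    np.fill_diagonal(cov, model.sill)
    return cov


def simulate_spatial_error(
    coords: np.ndarray,
    model: SpatialErrorModel,
    rng: np.random.Generator,
    n_fields: int = 1,
) -> np.ndarray:
    """Draw zero-mean Gaussian field(s) over the sites.

    Returns an array of shape ``(n_sites,)`` for ``n_fields == 1`` else
    ``(n_fields, n_sites)``.  A zero-variance model returns exact zeros.

    Raises
    ------
    np.linalg.LinAlgError
        If the covariance is not positive definite even after a small
        jitter (can happen with the gaussian family at near-duplicate
        sites).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n < 1:
        raise ValueError("need at least one site")
    if model.sill == 0.0:
        out = np.zeros((n_fields, n))
        return out[0] if n_fields == 1 else out
    cov = covariance_matrix(coords, model)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * model.sill * np.eye(n))
    z = rng.standard_normal((n_fields, n))
    fields = z @ chol.T
    return fields[0] if n_fields == 1 else fields


def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    lag_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron semivariogram estimator, optionally pooled over replicates.

    Parameters
    ----------
    values
        Shape ``(n_sites,)`` or ``(n_fields, n_sites)``; replicate fields
        are pooled, which is how simulated-field honesty is checked.

    Returns
    -------
    (lag_centers, gamma_hat, n_pairs) over the requested lag bins.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.atleast_2d(np.asarray(values, dtype=float))
    d = pdist(coords)
    lag_edges = np.asarray(lag_edges, dtype=float)
    which = np.digitize(d, lag_edges) - 1
    n_bins = len(lag_edges) - 1
    # squared half-differences per pair, averaged over replicate fields
    iu = np.triu_indices(coords.shape[0], k=1)
    sq = 0.5 * np.mean((values[:, iu[0]] - values[:, iu[1]]) ** 2, axis=0)
    gamma = np.full(n_bins, np.nan)
    npairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = which == b
        npairs[b] = mask.sum()
        if npairs[b]:
            gamma[b] = sq[mask].mean()
    centers = 0.5 * (lag_edges[:-1] + lag_edges[1:])
    return centers, gamma, npairs


def morans_i(
    coords: np.ndarray,
    values: np.ndarray,
    rng: np.random.Generator | None = None,
    n_permutations: int = 199,
) -> dict:
    """Moran's I with inverse-distance weights and a permutation p-value.

    Used to check whether site-mean model residuals retain spatial
    autocorrelation.  The p-value is one-sided (positive autocorrelation).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 sites")
    d = squareform(pdist(coords))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        return {"I": 0.0, "expected": -1.0 / (n - 1), "p_value": 1.0}
    observed = n / w.sum() * (z @ w @ z) / denom
    p = np.nan
    if rng is not None:
        count = 0
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            i_perm = n / w.sum() * (zp @ w @ zp) / denom
            if i_perm >= observed:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return {"I": float(observed), "expected": -1.0 / (n - 1), "p_value": float(p)}
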