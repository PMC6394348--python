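"""Weighted additive age-at-length model with a spatial smooth.

The evaluation layer fits, to each aged sub-sample,

    age_i = alpha + s1(length_i) x sex_i + s2(lon_i, lat_i) + eps_i

a Gaussian additive model with a separate penalized length spline per sex
(sex also enters as a factor) and a bivariate tensor-product spline over
geographic location, estimated by penalized weighted least squares with
P-spline (second-order difference) penalties.  Observation weights carry the
size-specific within-site abundance so that sub-samples that are not
proportional to the catch (the length-stratified design by construction)
are re-weighted toward the population's length composition.

Smoothing parameters are selected by generalized cross-validation on a
log-spaced grid (one parameter for the two sex-specific length smooths, one
for the spatial smooth); a tiny ridge keeps the penalized normal equations
positive definite under the penalties' polynomial null spaces.

The interface follows the fit/results idiom: :class:`AgeGAM` is constructed
from data and ``fit()`` returns an :class:`AgeGAMResults` carrying
estimates, effective degrees of freedom, explained variance, residual
diagnostics and ``predict``/``summary`` methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .spatial import morans_i


@dataclass(frozen=True)
class GamSpec:
    """Structure and hyperparameters of the age model.

    ``length_df`` and ``spatial_df`` are marginal basis dimensions (the
    spatial smooth has ``spatial_df**2`` tensor coefficients).  With
    ``select_smoothing`` off, ``fixed_alphas`` are used as-is, which makes
    repeated holdout refits cheap and deterministic.
    """

    response: str = "otolith_age"
    length_df: int = 40
    spatial_df: int = 6
    degree: int = 3
    include_spatial: bool = True
    select_smoothing: bool = True
    alpha_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-3.0, 4.0))
    fixed_alphas: tuple[float, float] = (1.0, 1.0)
    ridge: float = 1e-7

    def __post_init__(self):
        if self.length_df < 4 or self.spatial_df < 4:
            raise ValueError("basis dimensions must be >= 4")


class _PSplineBasis:
    """Univariate P-spline basis on an equally spaced knot grid."""

    def __init__(self, lo: float, hi: float, n_basis: int, degree: int = 3):
        if hi <= lo:
            hi = lo + 1.0
        nseg = n_basis - degree
        h = (hi - lo) / nseg
        self.lo, self.hi, self.degree = lo, hi, degree
        interior = np.linspace(lo, hi, nseg + 1)  # exact boundary knots
        self.knots = np.concatenate(
            [lo - h * np.arange(degree, 0, -1), interior, hi + h * np.arange(1, degree + 1)]
        )
        self.n_basis = n_basis

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self, order: int = 2) -> np.ndarray:
        d = np.diff(np.eye(self.n_basis), n=order, axis=0)
        return d.T @ d


class AgeGAM:
    """Model object: data + spec; ``fit()`` returns :class:`AgeGAMResults`.

    Parameters
    ----------
    data
        Fish-level records with columns ``length_mm, sex, longitude,
        latitude`` and the response column named in ``spec.response``.
    weights
        Positive observation weights (rescaled to mean 1 internally);
        default uniform.
    """

    def __init__(self, data: pd.DataFrame, weights: np.ndarray | None = None, spec: GamSpec | None = None):
        self.spec = spec or GamSpec()
        required = {"length_mm", "sex", "longitude", "latitude", self.spec.response}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        if len(data) < 50:
            raise ValueError(f"need >= 50 records to fit, got {len(data)}")
        sexes = set(data["sex"].unique())
        if not {"male", "female"} <= sexes:
            raise ValueError("both sexes must be present in the sub-sample")
        self.data = data.reset_index(drop=True)
        if weights is None:
            weights = np.ones(len(data))
        weights = np.asarray(weights, dtype=float)
        if (weights <= 0).any():
            raise ValueError("weights must be strictly positive")
        self.weights = weights / weights.mean()
        self._build_bases()

    def _build_bases(self):
        d = self.data
        self._length_basis = _PSplineBasis(
            float(d["length_mm"].min()), float(d["length_mm"].max()), self.spec.length_df, self.spec.degree
        )
        self._lon_basis = _PSplineBasis(
            float(d["longitude"].min()), float(d["longitude"].max()), self.spec.spatial_df, self.spec.degree
        )
        self._lat_basis = _PSplineBasis(
            float(d["latitude"].min()), float(d["latitude"].max()), self.spec.spatial_df, self.spec.degree
        )

    # -- design ---------------------------------------------------------
    def _design(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        bl = self._length_basis.design(data["length_mm"].to_numpy())
        male = (data["sex"].to_numpy() == "male").astype(float)
        cols = [np.ones((n, 1)), male[:, None]]
        cols.append(bl * male[:, None])
        cols.append(bl * (1.0 - male)[:, None])
        if self.spec.include_spatial:
            b1 = self._lon_basis.design(data["longitude"].to_numpy())
            b2 = self._lat_basis.design(data["latitude"].to_numpy())
            tensor = (b1[:, :, None] * b2[:, None, :]).reshape(n, -1)
            cols.append(tensor)
        return np.hstack(cols)

    def _penalties(self) -> list[np.ndarray]:
        kl = self.spec.length_df
        p_len = self._length_basis.penalty()
        p = self.spec.length_df * 2 + 2
        if self.spec.include_spatial:
            p += self.spec.spatial_df**2
        s_len = np.zeros((p, p))
        s_len[2 : 2 + kl, 2 : 2 + kl] = p_len
        s_len[2 + kl : 2 + 2 * kl, 2 + kl : 2 + 2 * kl] = p_len
        penalties = [s_len]
        if self.spec.include_spatial:
            ks = self.spec.spatial_df
            p1 = self._lon_basis.penalty()
            p2 = self._lat_basis.penalty()
            tensor_pen = np.kron(p1, np.eye(ks)) + np.kron(np.eye(ks), p2)
            s_sp = np.zeros((p, p))
            s_sp[2 + 2 * kl :, 2 + 2 * kl :] = tensor_pen
            penalties.append(s_sp)
        return penalties

    # -- fitting --------------------------------------------------------
    def fit(self, alphas: tuple[float, ...] | None = None) -> "AgeGAMResults":
        """Fit by penalized WLS; smoothing by GCV unless ``alphas`` given."""
        y = self.data[self.spec.response].to_numpy(dtype=float)
        w = self.weights
        X = self._design(self.data)
        penalties = self._penalties()
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWy = X.T @ (w * y)
        ridge = self.spec.ridge * np.eye(X.shape[1])

        def solve(alpha_vec):
            A = XtWX + ridge
            for a, S in zip(alpha_vec, penalties):
                A = A + a * S
            beta = np.linalg.solve(A, XtWy)
            edf = float(np.trace(np.linalg.solve(A, XtWX)))
            return beta, edf, A

        if alphas is not None:
            alpha_vec = tuple(alphas)
        elif not self.spec.select_smoothing:
            alpha_vec = self.spec.fixed_alphas[: len(penalties)]
        else:
            n = len(y)
            best = (np.inf, None)
            grid = self.spec.alpha_grid
            candidates = (
                [(a,) for a in grid]
                if len(penalties) == 1
                else [(a1, a2) for a1 in grid for a2 in grid]
            )
            for cand in candidates:
                beta, edf, _ = solve(cand)
                rss = float(w @ (y - X @ beta) ** 2)
                gcv = n * rss / max(n - edf, 1e-8) ** 2
                if gcv < best[0]:
                    best = (gcv, cand)
            alpha_vec = best[1]

        beta, edf, A = solve(alpha_vec)
        fitted = X @ beta
        resid = y - fitted
        rss = float(w @ resid**2)
        ybar = float(np.average(y, weights=w))
        tss = float(w @ (y - ybar) ** 2)
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        n = len(y)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - edf, 1.0) if tss > 0 else np.nan
        return AgeGAMResults(
            model=self,
            params=beta,
            alphas=tuple(float(a) for a in alpha_vec),
            edf=edf,
            fitted_values=fitted,
            resid=resid,
            weighted_rss=rss,
            pct_variance_explained=100.0 * r2,
            adj_r_squared=adj_r2,
            sigma2=rss / max(n - edf, 1.0),
        )


@dataclass
class AgeGAMResults:
    """Fit results: coefficients, smoothness, fit quality, diagnostics."""

    model: AgeGAM
    params: np.ndarray
    alphas: tuple[float, ...]
    edf: float
    fitted_values: np.ndarray
    resid: np.ndarray
    weighted_rss: float
    pct_variance_explained: float
    adj_r_squared: float
    sigma2: float
    _extrapolated: int = field(default=0, init=False)

    @property
    def nobs(self) -> int:
        return len(self.model.data)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Continuous age predictions at new covariates.

        Covariates outside the training range are clamped to it; the number
        of clamped rows is recorded in ``last_extrapolated`` rather than
        silently ignored.
        """
        lb, lob, lab = self.model._length_basis, self.model._lon_basis, self.model._lat_basis
        out_of_hull = (
            (data["length_mm"].to_numpy() < lb.lo)
            | (data["length_mm"].to_numpy() > lb.hi)
            | (data["longitude"].to_numpy() < lob.lo)
            | (data["longitude"].to_numpy() > lob.hi)
            | (data["latitude"].to_numpy() < lab.lo)
            | (data["latitude"].to_numpy() > lab.hi)
        )
        self._extrapolated = int(out_of_hull.sum())
        X = self.model._design(data)
        return X @ self.params

    @property
    def last_extrapolated(self) -> int:
        """Rows clamped to the training hull in the last ``predict`` call."""
        return self._extrapolated

    def length_effect(self, length_mm: np.ndarray, sex: str) -> np.ndarray:
        """Fitted age-at-length curve for one sex at the training centroid."""
        grid = pd.DataFrame(
            {
                "length_mm": np.asarray(length_mm, dtype=float),
                "sex": sex,
                "longitude": float(self.model.data["longitude"].mean()),
                "latitude": float(self.model.data["latitude"].mean()),
            }
        )
        return self.predict(grid)

    def residual_spatial_autocorrelation(
        self, rng: np.random.Generator | None = None, n_permutations: int = 199
    ) -> dict:
        """Moran's I of site-mean residuals (diagnostic for the spatial term)."""
        d = self.model.data.assign(_resid=self.resid)
        site = d.groupby(["longitude", "latitude"], as_index=False)["_resid"].mean()
        return morans_i(
            site[["longitude", "latitude"]].to_numpy(), site["_resid"].to_numpy(), rng, n_permutations
        )

    def diagnostics(self) -> dict:
        """Normality (D'Agostino) and heteroscedasticity (Breusch-Pagan-style)."""
        from scipy import stats

        resid = self.resid
        norm_stat, norm_p = stats.normaltest(resid)
        # squared residuals vs fitted: slope test for variance trend
        slope = stats.linregress(self.fitted_values, resid**2)
        return {
            "normality_stat": float(norm_stat),
            "normality_p": float(norm_p),
            "heteroscedasticity_slope_p": float(slope.pvalue),
        }

    def summary(self) -> str:
        lines = [
            "Weighted additive age-at-length model",
            "=" * 48,
            f"n obs                 {self.nobs:>10d}",
            f"effective df          {self.edf:>10.2f}",
            f"smoothing (length)    {self.alphas[0]:>10.3g}",
        ]
        if self.model.spec.include_spatial and len(self.alphas) > 1:
            lines.append(f"smoothing (spatial)   {self.alphas[1]:>10.3g}")
        lines += [
            f"% variance explained  {self.pct_variance_explained:>10.2f}",
            f"adj. R-squared        {self.adj_r_squared:>10.4f}",
            f"residual sigma^2      {self.sigma2:>10.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)
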