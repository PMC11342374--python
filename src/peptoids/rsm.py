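"""Response-surface structure-activity model over the lipid-block factors.

Ordinary least squares on the full second-order model matrix (intercept,
mains, effect-coded categorical, all pairwise interactions, quadratics).
Screening responses are fit as log10 of total flux by default — in vivo
bioluminescence spans orders of magnitude — with raw-scale fitting
available.

Rank deficiency (e.g. a design where every point has nonlinear identity
``none``, zeroing the categorical column and its interactions) is
resolved by a pivoted QR: aliased columns are dropped deterministically
and recorded on the fit.

The feasible optimum is located by exhaustive evaluation over the
(finite) feasible factor set, and its uncertainty by a parametric
bootstrap: coefficient vectors are drawn from the fitted multivariate
normal, each draw is re-optimized, and per-factor mean +- SD are
reported — the same shape of summary as a "model predicted" optimum row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .design_space import FactorPoint
from .doe import CONTINUOUS, ModelMatrixSpec, model_matrix
from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OptimumReport:
    """Feasible optimum with bootstrap per-factor uncertainty."""

    best_point: FactorPoint
    predicted: float
    se: float
    factor_mean: dict
    factor_sd: dict
    identity_mode: str
    identity_share: float
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in zip((*CONTINUOUS, "nonlinear_id"),
                               self.best_point.as_tuple()):
            row = {"factor": name, "best": value}
            if name in self.factor_mean:
                row["boot_mean"] = self.factor_mean[name]
                row["boot_sd"] = self.factor_sd[name]
            else:
                row["boot_mode"] = self.identity_mode
                row["boot_share"] = self.identity_share
            rows.append(row)
        return pd.DataFrame(rows)


class ResponseSurface(RegressorMixin, BaseEstimator):
    """Full-quadratic OLS response-surface model.

    Parameters
    ----------
    spec : ModelMatrixSpec, optional
        Term set and scaling ranges. Pass the spec fitted on the candidate
        space so that prediction reuses the same [-1, 1] scaling;
        otherwise ranges are derived from the training points.
    rank_tol : float, default 1e-8
        Relative pivot threshold below which trailing columns are
        declared aliased and dropped.

    Attributes
    ----------
    coef_ : pd.Series — estimates for retained terms.
    cov_ : pd.DataFrame — coefficient covariance (retained terms).
    residual_sd_, r_squared_, n_obs_ : fit summaries.
    dropped_terms_ : tuple of aliased column names removed.
    """

    def __init__(self, spec: ModelMatrixSpec | None = None,
                 rank_tol: float = 1e-8):
        self.spec = spec
        self.rank_tol = rank_tol

    def fit(self, points, y):
        y = np.asarray(y, dtype=float)
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            raise FitError(f"non-finite response values at rows {bad.tolist()}")
        Xdf, spec = model_matrix(points, self.spec, strict_ranges=False)
        if len(Xdf) != len(y):
            raise FitError("points/response length mismatch")
        X = Xdf.to_numpy()
        n, p = X.shape
        # pivoted QR: keep the first r pivots, drop trailing aliased columns
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        r = int(np.sum(diag > self.rank_tol * max(diag[0], 1e-300)))
        keep = np.sort(piv[:r])
        dropped = tuple(Xdf.columns[j] for j in np.sort(piv[r:]))
        if n < r:
            raise FitError(f"{n} observations for {r} retained columns")
        Xk = X[:, keep]
        names = [Xdf.columns[j] for j in keep]
        XtX = Xk.T @ Xk
        beta = np.linalg.solve(XtX, Xk.T @ y)
        resid = y - Xk @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        dof = n - r
        sigma2 = rss / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(XtX)
        self.spec_ = spec
        self.terms_ = tuple(names)
        self.dropped_terms_ = dropped
        self.coef_ = pd.Series(beta, index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.residual_sd_ = float(np.sqrt(sigma2))
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else 1.0
        self.n_obs_ = n
        if dropped:
            logger.warning("dropped aliased model terms: %s", list(dropped))
        return self

    def _design(self, points) -> np.ndarray:
        Xdf, _ = model_matrix(points, self.spec_)
        X = Xdf[list(self.terms_)].to_numpy()
        scaled = Xdf[[c for c in CONTINUOUS if c in Xdf.columns]].to_numpy()
        if np.any(np.abs(scaled) > 1.0 + 1e-9):
            logger.warning("prediction outside the fitted factor ranges "
                           "(extrapolation)")
        return X

    def predict(self, points, return_se: bool = False):
        X = self._design(points)
        yhat = X @ self.coef_.to_numpy()
        if not return_se:
            return yhat
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov_.to_numpy(), X))
        return yhat, se

    def report(self) -> dict:
        """JSON-serializable model summary."""
        se = np.sqrt(np.diag(self.cov_.to_numpy()))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.coef_.to_numpy() / se, np.inf)
        return {
            "terms": list(self.terms_),
            "coefficients": self.coef_.round(10).to_dict(),
            "standard_errors": dict(zip(self.terms_, np.round(se, 10))),
            "t_statistics": dict(zip(self.terms_, np.round(t, 6))),
            "r_squared": round(float(self.r_squared_), 10),
            "residual_sd": round(float(self.residual_sd_), 10),
            "n_obs": int(self.n_obs_),
            "dropped_terms": list(self.dropped_terms_),
            "ranges": {k: list(v) for k, v in self.spec_.ranges.items()},
        }


def fit_rsm(points, response, spec: ModelMatrixSpec | None = None,
            **kwargs) -> ResponseSurface:
    """Fit the quadratic response-surface model (thin wrapper)."""
    return ResponseSurface(spec=spec, **kwargs).fit(points, response)


def predict(fit: ResponseSurface, points, return_se: bool = True):
    return fit.predict(points, return_se=return_se)


def _lex_argmax(values: np.ndarray, points: list[FactorPoint]) -> int:
    """Index of the max value; exact ties resolve to the lexicographically
    smallest factor point."""
    best = np.max(values)
    tied = np.flatnonzero(values >= best - 1e-9 * max(1.0, abs(best)))
    return int(min(tied, key=lambda i: points[i].as_tuple()))


def find_optimum(fit: ResponseSurface, feasible, n_boot: int = 1000,
                 seed: int = 0) -> OptimumReport:
    """Exhaustive argmax of the fitted surface over the feasible set.

    Uncertainty by parametric bootstrap: ``n_boot`` coefficient vectors
    are drawn from N(beta, Cov) and each draw re-optimized; per-factor
    mean +- SD (and the modal nonlinear identity with its share) summarize
    the re-optimized optima. ``n_boot=0`` gives the point estimate only.
    """
    points = list(feasible)
    if not points:
        raise ValidationError("feasible set is empty")
    points = sorted(points, key=lambda p: p.as_tuple())
    X = fit._design(points)
    beta = fit.coef_.to_numpy()
    yhat = X @ beta
    i_best = _lex_argmax(yhat, points)
    best = points[i_best]
    se = float(np.sqrt(X[i_best] @ fit.cov_.to_numpy() @ X[i_best]))
    factor_mean, factor_sd = {}, {}
    identity_mode, identity_share = best.nonlinear_id, 1.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        cov = fit.cov_.to_numpy()
        # PSD square root via eigendecomposition (covariance may be singular)
        w, V = np.linalg.eigh((cov + cov.T) / 2)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        draws = beta[None, :] + rng.standard_normal((n_boot, len(beta))) @ L.T
        preds = draws @ X.T                      # n_boot x n_points
        opt_pts = [points[_lex_argmax(row, points)] for row in preds]
        arr = np.array([p.as_tuple()[:3] for p in opt_pts], dtype=float)
        for j, name in enumerate(CONTINUOUS):
            factor_mean[name] = float(arr[:, j].mean())
            factor_sd[name] = float(arr[:, j].std(ddof=0))
        ids = pd.Series([p.nonlinear_id for p in opt_pts])
        identity_mode = ids.value_counts().idxmax()
        identity_share = float((ids == identity_mode).mean())
    else:
        for j, name in enumerate(CONTINUOUS):
            factor_mean[name] = float(best.as_tuple()[j])
            factor_sd[name] = 0.0
    return OptimumReport(best_point=best, predicted=float(yhat[i_best]),
                         se=se, factor_mean=factor_mean, factor_sd=factor_sd,
                         identity_mode=identity_mode,
                         identity_share=identity_share, n_boot=n_boot)


def contour_grid(fit: ResponseSurface, factor_x: str, factor_y: str,
                 fixed: dict, nx: int = 41, ny: int = 41,
                 bounds_x=None, bounds_y=None) -> pd.DataFrame:
    """Rectangular grid of predictions over two continuous factors.

    Remaining factors are held at the values in ``fixed`` (which must
    include the nonlinear identity). Grid bounds default to the fitted
    candidate ranges.
    """
    for name in (factor_x, factor_y):
        if name not in CONTINUOUS:
            raise ValidationError(f"unknown continuous factor {name!r}")
    missing = [f for f in (*CONTINUOUS, "nonlinear_id")
               if f not in (factor_x, factor_y) and f not in fixed]
    if missing:
        raise ValidationError(f"fixed values required for {missing}")
    bx = bounds_x or fit.spec_.ranges[factor_x]
    by = bounds_y or fit.spec_.ranges[factor_y]
    xs = np.linspace(bx[0], bx[1], nx)
    ys = np.linspace(by[0], by[1], ny)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    df = pd.DataFrame({factor_x: XX.ravel(), factor_y: YY.ravel()})
    for f in (*CONTINUOUS, "nonlinear_id"):
        if f not in df.columns:
            df[f] = fixed[f]
    df["prediction"] = fit.predict(df[[*CONTINUOUS, "nonlinear_id"]])
    return df[[factor_x, factor_y, "prediction"]]
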