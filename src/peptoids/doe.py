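"""Second-order model matrix and D-optimal design selection.

The response-surface model treats the three count factors (lipid
monomers, total lipid carbons, nonlinear monomers) as continuous —
affinely scaled to [-1, +1] over the candidate range — and the nonlinear
identity as a categorical factor, effect-coded +1 for Ehx, -1 for Ole,
0 for none. The full model has 14 named columns: intercept, 3 continuous
mains, the effect-coded column, all 6 pairwise interactions, and 3
continuous quadratics.

Design selection maximizes det(X'X) by Fedorov exchange: starting from a
seeded random subset of the candidates, the single swap (one point out,
one in) with the largest determinant gain is applied until no swap
improves, with multi-start restarts. A small ridge stabilizes the inverse
during the search; the reported criterion is ridge-free. Determinant
gains use the classical rank-one delta function

    delta(i, j) = d(x_j) - d(x_i) - [d(x_i) d(x_j) - d(x_i, x_j)^2]

where d(x, y) = x' M^-1 y and d(x) = d(x, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design_space import CandidateSet
from .errors import DesignError, ValidationError

CONTINUOUS = ("n_lipid_monomers", "total_lipid_carbons", "n_nonlinear")
CATEGORICAL = "nonlinear_id"
EFFECT_CODE = {"Ehx": 1.0, "Ole": -1.0, "none": 0.0}

_MAINS = (*CONTINUOUS, CATEGORICAL)
_INTERACTIONS = tuple(f"{a}:{b}" for i, a in enumerate(_MAINS)
                      for b in _MAINS[i + 1:])
_QUADRATICS = tuple(f"{f}^2" for f in CONTINUOUS)

#: Fixed column order of the full 14-term model.
FULL_TERMS = ("intercept", *_MAINS, *_INTERACTIONS, *_QUADRATICS)


@dataclass
class ModelMatrixSpec:
    """Term set and scaling constants of the quadratic model matrix.

    ``ranges`` maps each continuous factor to its (min, max) over the
    candidate space; it is filled on first use and then reused so that
    predictions are made on the same scale the model was built on.
    """

    terms: tuple[str, ...] = FULL_TERMS
    ranges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in FULL_TERMS]
        if unknown:
            raise ValidationError(f"unknown model terms {unknown}")

    def scale(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.ranges[name]
        if hi == lo:  # degenerate factor: centered, constant column
            return np.asarray(values, dtype=float) - lo
        return (2.0 * values - (hi + lo)) / (hi - lo)


def _points_frame(points) -> pd.DataFrame:
    if isinstance(points, CandidateSet):
        return points.to_frame()
    if isinstance(points, pd.DataFrame):
        return points
    rows = [dict(zip((*CONTINUOUS, CATEGORICAL), p.as_tuple()))
            for p in points]
    return pd.DataFrame(rows)


def model_matrix(points, spec: ModelMatrixSpec | None = None,
                 strict_ranges: bool = True):
    """Build the named design matrix for a list of factor points.

    Returns ``(X, spec)`` where X is a DataFrame with one row per point
    and the spec carries the scaling constants for reuse at prediction
    time. A degenerate (max = min) continuous range raises when
    ``strict_ranges`` (the design-selection path); otherwise the factor
    yields a constant zero column that downstream rank handling drops as
    aliased.
    """
    df = _points_frame(points)
    if len(df) < 1:
        raise ValidationError("model_matrix requires at least one point")
    spec = spec or ModelMatrixSpec()
    used = {f for t in spec.terms for f in t.replace("^2", "").split(":")
            if f in CONTINUOUS}
    if not spec.ranges:
        for name in sorted(used, key=CONTINUOUS.index):
            lo, hi = float(df[name].min()), float(df[name].max())
            if hi == lo and strict_ranges:
                raise DesignError(
                    f"degenerate candidate range for {name}: all values {lo}")
            spec.ranges[name] = (lo, hi)
    cols = {"intercept": np.ones(len(df))}
    for name in used:
        cols[name] = spec.scale(name, df[name].to_numpy(dtype=float))
    if any(CATEGORICAL in t for t in spec.terms):
        cols[CATEGORICAL] = (df[CATEGORICAL].map(EFFECT_CODE)
                             .to_numpy(dtype=float))
    for term in spec.terms:
        if term in _INTERACTIONS:
            a, b = term.split(":")
            cols[term] = cols[a] * cols[b]
        elif term in _QUADRATICS:
            cols[term] = cols[term[:-2]] ** 2
    X = pd.DataFrame({t: cols[t] for t in spec.terms})
    return X, spec


def d_criterion(X: np.ndarray) -> float:
    """Ridge-free D-criterion det(X'X)."""
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return float(sign * np.exp(logdet)) if np.isfinite(logdet) else 0.0


def _sm_add(Minv: np.ndarray, x: np.ndarray, sign: float) -> np.ndarray:
    """Sherman-Morrison update of M^-1 for M +- x x'."""
    Mx = Minv @ x
    denom = 1.0 + sign * float(x @ Mx)
    return Minv - sign * np.outer(Mx, Mx) / denom


class DOptimalDesigner(BaseEstimator):
    """D-optimal subset selection by multi-start Fedorov exchange.

    Parameters
    ----------
    n_runs : int, default 34
        Number of distinct design points to select.
    spec : ModelMatrixSpec, optional
        Model terms; the full 14-term quadratic model by default.
    n_starts : int, default 20
        Random restarts; the best final criterion wins.
    ridge : float, default 1e-9
        Diagonal stabilizer on X'X during the search only.
    random_state : int, default 0

    Attributes
    ----------
    support_ : list of int — selected candidate indices (sorted).
    criterion_ : float — ridge-free det(X'X) of the selected design.
    spec_ : ModelMatrixSpec with scaling ranges filled.
    """

    def __init__(self, n_runs: int = 34, spec: ModelMatrixSpec | None = None,
                 n_starts: int = 20, ridge: float = 1e-9,
                 random_state: int = 0):
        self.n_runs = n_runs
        self.spec = spec
        self.n_starts = n_starts
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, candidates, y=None):
        spec = self.spec or ModelMatrixSpec()
        spec = replace(spec, ranges=dict(spec.ranges))
        Xdf, spec = model_matrix(candidates, spec)
        X = Xdf.to_numpy()
        N, p = X.shape
        n = self.n_runs
        if n < p:
            raise DesignError(
                f"n_runs={n} below model column count {p}: singular by "
                f"construction")
        if n > N:
            raise DesignError(f"n_runs={n} exceeds candidate count {N}")
        self.spec_ = spec
        if n == N:
            self.support_ = list(range(N))
            self.criterion_ = d_criterion(X)
            return self
        rng = np.random.default_rng(self.random_state)
        best_idx, best_crit = None, -np.inf
        for _ in range(self.n_starts):
            idx = self._exchange(X, sorted(rng.choice(N, size=n, replace=False)))
            crit = d_criterion(X[idx])
            if best_idx is None or crit > best_crit + 1e-12 * abs(best_crit):
                best_idx, best_crit = idx, crit
        self.support_ = sorted(best_idx)
        self.criterion_ = d_criterion(X[self.support_])
        return self

    def _exchange(self, X: np.ndarray, idx: list[int]) -> list[int]:
        N, p = X.shape
        idx = list(idx)
        M = X[idx].T @ X[idx] + self.ridge * np.eye(p)
        Minv = np.linalg.inv(M)
        while True:
            in_design = np.zeros(N, dtype=bool)
            in_design[idx] = True
            A = X @ Minv.T                       # N x p
            d_all = np.einsum("ij,ij->i", A, X)  # d(x) for all candidates
            D = X[idx] @ Minv @ X.T              # n x N, d(x_i, x_j)
            d_des = d_all[idx]
            delta = (d_all[None, :] - d_des[:, None]
                     - (d_des[:, None] * d_all[None, :] - D ** 2))
            delta[:, in_design] = -np.inf
            gain = delta.max()
            if gain <= 1e-10:
                return idx
            # tie-break: lowest (out-position, in-index)
            i, j = np.unravel_index(int(np.argmax(delta)), delta.shape)
            x_out, x_in = X[idx[i]], X[j]
            Minv = _sm_add(Minv, x_out, -1.0)
            Minv = _sm_add(Minv, x_in, +1.0)
            idx[i] = int(j)


def select_design(candidates, n_runs: int, seed: int = 0,
                  n_starts: int = 20, spec: ModelMatrixSpec | None = None):
    """Select a D-optimal subset of a CandidateSet (or point list).

    Returns ``(subset, designer)``: the selected CandidateSet subset (or
    index list for plain point lists) and the fitted designer carrying the
    criterion and scaling spec.
    """
    des = DOptimalDesigner(n_runs=n_runs, spec=spec, n_starts=n_starts,
                           random_state=seed).fit(candidates)
    if isinstance(candidates, CandidateSet):
        return candidates.subset(des.support_), des
    return des.support_, des
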