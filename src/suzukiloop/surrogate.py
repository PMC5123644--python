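"""Log-scale response surface shared across candidates.

The model for the log objective z = ln(response + eps) of candidate k at coded
continuous settings u is

    z = a_k + b_k * u_T + sum_j c_j u_j + sum_{i<j} d_ij u_i u_j + sum_j e_j u_j^2

with per-candidate intercepts a_k ("pre-exponential offsets" — multiplicative
candidate effects on the response scale) and per-candidate temperature slopes
b_k ("temperature offsets"), while linear terms for the remaining variables,
all pairwise interactions, and all quadratics are shared across candidates.
There is no global intercept and no shared linear temperature column: both are
absorbed by the candidate blocks, keeping the design matrix full rank.

Temperature can enter the candidate-specific terms either as plain coded T
(default) or through an Arrhenius-style transform of -1000/T(K) rescaled to
[-1, 1] (``temp_coding="arrhenius"``).  Residence time is coded on a log scale
by default (``time_coding="log"``): with first-order kinetics over a decade of
times, ln t is the natural regressor and a quadratic in plain t badly distorts
saturating yield curves near the long-time boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .design_space import (
    TEMPERATURE,
    TIME,
    DesignSpace,
    ExperimentRecord,
    ReactionCondition,
    scale_matrix,
)
from .errors import DomainError, FitError, RankDeficientFitWarning

#: additive guard before taking logs, so zero-yield droplets stay finite
LOG_EPS = 0.01

TEMP_CODINGS = ("coded", "arrhenius")
TIME_CODINGS = ("coded", "log")


@dataclass(frozen=True)
class FeatureSpec:
    """Column layout of the feature matrix (order is part of the contract)."""

    candidates: tuple[str, ...]
    variables: tuple[str, ...]
    temp_coding: str = "coded"
    temp_bounds: tuple[float, float] = (0.0, 1.0)  # native T range, for arrhenius coding
    time_coding: str = "coded"
    time_bounds: tuple[float, float] = (1.0, 10.0)  # native t range, for log coding

    def __post_init__(self) -> None:
        if self.temp_coding not in TEMP_CODINGS:
            raise DomainError(f"temp_coding must be one of {TEMP_CODINGS}")
        if self.time_coding not in TIME_CODINGS:
            raise DomainError(f"time_coding must be one of {TIME_CODINGS}")

    @property
    def K(self) -> int:
        return len(self.candidates)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def temp_index(self) -> int | None:
        try:
            return self.variables.index(TEMPERATURE)
        except ValueError:
            return None

    @property
    def time_index(self) -> int | None:
        try:
            return self.variables.index(TIME)
        except ValueError:
            return None

    @property
    def n_features(self) -> int:
        p, K = self.p, self.K
        n_lin = p - 1 if self.temp_index is not None else p
        return 2 * K + n_lin + (p * (p - 1)) // 2 + p

    def column_names(self) -> list[str]:
        names = [f"intercept[{c}]" for c in self.candidates]
        names += [f"T_slope[{c}]" for c in self.candidates]
        ti = self.temp_index
        names += [f"lin[{v}]" for i, v in enumerate(self.variables) if i != ti]
        names += [
            f"int[{a}*{b}]" for a, b in combinations(self.variables, 2)
        ]
        names += [f"quad[{v}]" for v in self.variables]
        return names

    def candidate_index(self, cand: str) -> int:
        try:
            return self.candidates.index(cand)
        except ValueError:
            raise DomainError(f"candidate {cand!r} not in model roster") from None


def _coded_temperature(spec: FeatureSpec, u: np.ndarray, x_native: np.ndarray) -> np.ndarray:
    """Per-run temperature regressor for the candidate-specific terms."""
    ti = spec.temp_index
    if ti is None:
        raise DomainError("space has no temperature variable")
    if spec.temp_coding == "coded":
        return u[:, ti]
    t_lo, t_hi = spec.temp_bounds
    s = -1000.0 / (x_native[:, ti] + 273.15)
    s_lo = -1000.0 / (t_lo + 273.15)
    s_hi = -1000.0 / (t_hi + 273.15)
    return 2.0 * (s - s_lo) / (s_hi - s_lo) - 1.0


def feature_matrix(
    x_native: np.ndarray,
    cand_idx: np.ndarray,
    space: DesignSpace,
    spec: FeatureSpec,
) -> np.ndarray:
    """(n, m) feature matrix for native-unit settings and candidate indices."""
    x_native = np.atleast_2d(np.asarray(x_native, dtype=float))
    cand_idx = np.asarray(cand_idx, dtype=int)
    n = x_native.shape[0]
    u = scale_matrix(x_native, space)
    tj = spec.time_index
    if tj is not None and spec.time_coding == "log":
        lo, hi = spec.time_bounds
        u[:, tj] = (
            2.0 * (np.log(x_native[:, tj]) - np.log(lo)) / (np.log(hi) - np.log(lo)) - 1.0
        )
    K, p = spec.K, spec.p
    ti = spec.temp_index

    X = np.zeros((n, spec.n_features))
    rows = np.arange(n)
    X[rows, cand_idx] = 1.0
    col = K
    if ti is not None:
        uT = _coded_temperature(spec, u, x_native)
        X[rows, K + cand_idx] = uT
        col = 2 * K
        lin_vars = [j for j in range(p) if j != ti]
    else:
        # no temperature variable: candidate slopes degenerate to zero columns;
        # keep layout but fill with zeros (rank handled by pseudo-inverse)
        col = 2 * K
        lin_vars = list(range(p))
    for j in lin_vars:
        X[:, col] = u[:, j]
        col += 1
    for i, j in combinations(range(p), 2):
        X[:, col] = u[:, i] * u[:, j]
        col += 1
    for j in range(p):
        X[:, col] = u[:, j] ** 2
        col += 1
    assert col == spec.n_features
    return X


def build_features(
    cond: ReactionCondition, space: DesignSpace, spec: FeatureSpec
) -> np.ndarray:
    """Feature vector for a single condition."""
    space.validate_condition(cond)
    cand = space.candidate(cond.candidate)
    if not cand.active:
        raise DomainError(f"candidate {cond.candidate!r} is inactive")
    ci = spec.candidate_index(cond.candidate)
    return feature_matrix(
        np.asarray(cond.x)[None, :], np.array([ci]), space, spec
    )[0]


def make_feature_spec(
    space: DesignSpace, temp_coding: str = "coded", time_coding: str = "log"
) -> FeatureSpec:
    cands = space.active_candidates()
    bounds = (0.0, 1.0)
    if TEMPERATURE in space.names:
        v = space.var(TEMPERATURE)
        bounds = (v.lower, v.upper)
    t_bounds = (1.0, 10.0)
    if TIME in space.names:
        tv = space.var(TIME)
        t_bounds = (tv.lower, tv.upper)
        if tv.lower <= 0:
            time_coding = "coded"  # log transform needs a positive lower bound
    return FeatureSpec(
        candidates=cands,
        variables=space.names,
        temp_coding=temp_coding,
        temp_bounds=bounds,
        time_coding=time_coding,
        time_bounds=t_bounds,
    )


@dataclass
class SurrogateModel:
    """Fitted response surface on the log scale.

    ``rowspace`` holds an orthonormal basis (rank x m) of the identified
    coefficient directions; predictions at feature vectors with a component
    outside it are minimum-norm extrapolations the data say nothing about,
    and :meth:`identified` flags them so searches can skip such points.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    dof: int
    feature_spec: FeatureSpec
    space: DesignSpace
    rank: int = 0
    eps: float = LOG_EPS
    n_obs: int = 0
    rowspace: np.ndarray | None = None
    gram_pinv: np.ndarray | None = None  # (X^T X)^+, for leverage

    def leverage(self, F: np.ndarray) -> np.ndarray:
        """Prediction leverage h(x) = f^T (X^T X)^+ f for each feature row."""
        F = np.atleast_2d(F)
        if self.gram_pinv is None:
            if self.sigma2 > 0:
                return np.einsum("ij,jk,ik->i", F, self.cov_beta, F) / self.sigma2
            return np.zeros(F.shape[0])
        return np.einsum("ij,jk,ik->i", F, self.gram_pinv, F)

    def identified(self, F: np.ndarray, tol: float = 1e-6,
                   leverage_cap: float | None = None) -> np.ndarray:
        """Mask of feature rows the fit can genuinely predict.

        A row must lie in the identified row space (else the minimum-norm fit
        says nothing about it) and, when ``leverage_cap`` is given, have
        prediction leverage at most that cap — points beyond the sampled
        design region are extrapolations even for a full-rank fit.
        """
        F = np.atleast_2d(F)
        if self.rowspace is None or self.rank == F.shape[1]:
            ok = np.ones(F.shape[0], dtype=bool)
        else:
            proj = F @ self.rowspace.T @ self.rowspace
            resid = np.linalg.norm(F - proj, axis=1)
            scale = np.maximum(np.linalg.norm(F, axis=1), 1.0)
            ok = resid <= tol * scale
        if leverage_cap is not None:
            ok = ok & (self.leverage(F) <= leverage_cap)
        return ok

    def predict(self, cond: ReactionCondition) -> tuple[float, float]:
        """(mean log response, standard error of the mean log response)."""
        f = build_features(cond, self.space, self.feature_spec)
        mean = float(f @ self.beta)
        se = float(np.sqrt(max(0.0, f @ self.cov_beta @ f)))
        return mean, se

    def predict_many(
        self, x_native: np.ndarray, cand_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        F = feature_matrix(x_native, cand_idx, self.space, self.feature_spec)
        return self.predict_features(F)

    def predict_features(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = F @ self.beta
        var = np.einsum("ij,jk,ik->i", F, self.cov_beta, F)
        return mean, np.sqrt(np.clip(var, 0.0, None))

    def predict_response(self, cond: ReactionCondition) -> float:
        """Point prediction on the response scale, floored at zero."""
        mean, _ = self.predict(cond)
        return max(0.0, float(np.exp(mean) - self.eps))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "sigma2": self.sigma2,
            "dof": self.dof,
            "rank": self.rank,
            "eps": self.eps,
            "n_obs": self.n_obs,
            "columns": self.feature_spec.column_names(),
            "candidates": list(self.feature_spec.candidates),
            "variables": list(self.feature_spec.variables),
            "temp_coding": self.feature_spec.temp_coding,
            "time_coding": self.feature_spec.time_coding,
        }


def fit(
    records: Iterable[ExperimentRecord],
    space: DesignSpace,
    temp_coding: str = "coded",
    eps: float = LOG_EPS,
    time_coding: str = "log",
) -> SurrogateModel:
    """Ordinary least squares of ln(response + eps) on the shared feature matrix.

    Failed droplets (NaN yield) are excluded.  A rank-deficient matrix is
    handled with a pseudo-inverse (and a :class:`RankDeficientFitWarning`);
    degrees of freedom are ``n_obs - rank``.  Raises :class:`FitError` when all
    responses are zero or no residual degrees of freedom remain.
    """
    recs = [r for r in records if r.ok]
    if not recs:
        raise FitError("no successful experiments to fit")
    if any(r.response < 0 for r in recs):
        raise FitError("negative responses cannot be log-transformed")
    if all(r.response == 0 for r in recs):
        raise FitError(
            "all observed responses are zero; widen the explored conditions before fitting"
        )
    spec = make_feature_spec(space, temp_coding, time_coding)
    x_native = np.array([r.condition.x for r in recs])
    cand_idx = np.array([spec.candidate_index(r.condition.candidate) for r in recs])
    X = feature_matrix(x_native, cand_idx, space, spec)
    z = np.log(np.array([r.response for r in recs]) + eps)

    n, m = X.shape
    # one SVD provides the minimum-norm OLS solution, its covariance, and the
    # identified row space with a single consistent rank cutoff
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    cutoff = np.finfo(float).eps * max(n, m) * (s[0] if len(s) else 0.0)
    keep = s > cutoff
    rank = int(np.sum(keep))
    if rank < m:
        warnings.warn(
            f"feature matrix rank {rank} < {m} columns; coefficients are the "
            "minimum-norm solution and some directions are unidentified",
            RankDeficientFitWarning,
            stacklevel=2,
        )
    dof = n - rank
    if dof < 1:
        raise FitError(
            f"no residual degrees of freedom (n={n}, rank={rank}); collect more experiments"
        )
    Vr = Vt[keep]
    sr = s[keep]
    beta = Vr.T @ ((U[:, keep].T @ z) / sr)
    resid = z - X @ beta
    sigma2 = float(resid @ resid) / dof
    gram_pinv = (Vr.T * (1.0 / sr**2)) @ Vr
    gram_pinv = 0.5 * (gram_pinv + gram_pinv.T)
    cov = sigma2 * gram_pinv
    return SurrogateModel(
        beta=beta,
        cov_beta=cov,
        sigma2=sigma2,
        dof=int(dof),
        feature_spec=spec,
        space=space,
        rank=rank,
        eps=eps,
        n_obs=n,
        rowspace=Vr if rank < m else None,
        gram_pinv=gram_pinv,
    )
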