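"""Pseudo-first-order protodeboronation / controlled-release kinetics.

Two coupled irreversible first-order steps describe the boron pool at a fixed
temperature: the pinacol boronate E hydrolyzes to the free boronic acid B at
rate k_h, and only the free acid protodeboronates, at rate k_p:

    E  --k_h-->  B  --k_p-->  (dead arene)

    dE/dt = -k_h E
    dB/dt =  k_h E - k_p B

Closed form with E(0) = BE0, B(0) = BA0:

    E(t) = BE0 exp(-k_h t)
    B(t) = BA0 exp(-k_p t) + BE0 k_h / (k_p - k_h) (exp(-k_h t) - exp(-k_p t))

degenerating to BE0 k t exp(-k t) for the release term when k_p = k_h = k.
When the two rates are matched, the ester acts as a controlled-release
reservoir and B(t) holds nearly constant over the working time window — the
regime that lets a slow catalyst couple an otherwise short-lived boronic acid.

Time courses are fit on the concentration scale by joint nonlinear least
squares over all runs; "BA_only" runs observe B(t) directly, "BA_plus_BE" runs
observe E(t) + B(t) (the ester hydrolyzes completely during analysis and is
quantified as the acid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, DomainError, FitError

OBSERVABLES = ("BA_only", "BA_plus_BE")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants (1/min) and initial concentrations (M)."""

    k_p: float
    k_h: float = 0.0
    BA0: float = 0.0
    BE0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_p < 0 or self.k_h < 0:
            raise ConfigurationError("rate constants must be >= 0")
        if self.BA0 < 0 or self.BE0 < 0:
            raise ConfigurationError("initial concentrations must be >= 0")
        if self.BA0 == 0 and self.BE0 == 0:
            raise ConfigurationError("BA0 and BE0 cannot both be zero")


@dataclass
class TimeCourse:
    """One measured concentration-vs-time run.

    ``observable`` says what the detector saw: the free boronic acid alone, or
    the combined ester + acid pool.  Initial concentrations default to the
    first measured point (runs are assumed to start from a pure species:
    BA_only from pure acid, BA_plus_BE from pure ester); pass ``ba0``/``be0``
    explicitly for mixed starts.
    """

    t: np.ndarray
    c: np.ndarray
    observable: str
    ba0: float | None = None
    be0: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.observable not in OBSERVABLES:
            raise ConfigurationError(
                f"observable must be one of {OBSERVABLES}, got {self.observable!r}"
            )
        if self.t.shape != self.c.shape or self.t.ndim != 1 or len(self.t) < 3:
            raise ConfigurationError("t and c must be equal-length 1-D arrays with >= 3 points")
        if np.any(np.diff(self.t) <= 0) or self.t[0] < 0:
            raise ConfigurationError("t must be strictly increasing and >= 0")
        if np.any(self.c < 0):
            raise ConfigurationError("concentrations must be >= 0")

    def initials(self) -> tuple[float, float]:
        """(BA0, BE0) for this run, inferred from the first point if not given."""
        if self.ba0 is not None or self.be0 is not None:
            return float(self.ba0 or 0.0), float(self.be0 or 0.0)
        if self.observable == "BA_only":
            return float(self.c[0]), 0.0
        return 0.0, float(self.c[0])


# ---------------------------------------------------------------------------
# closed-form profiles
# ---------------------------------------------------------------------------

def profiles(
    params: KineticParams, t: np.ndarray | Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(BE(t), BA(t), combined(t)) from the closed-form solution."""
    t = np.asarray(t, dtype=float)
    k_p, k_h = params.k_p, params.k_h
    be = params.BE0 * np.exp(-k_h * t)
    ba = params.BA0 * np.exp(-k_p * t)
    if params.BE0 > 0 and k_h > 0:
        if np.isclose(k_p, k_h, rtol=1e-9, atol=1e-15):
            k = 0.5 * (k_p + k_h)
            ba = ba + params.BE0 * k * t * np.exp(-k * t)
        else:
            ba = ba + params.BE0 * k_h / (k_p - k_h) * (np.exp(-k_h * t) - np.exp(-k_p * t))
    ba = np.maximum(ba, 0.0)
    return be, ba, be + ba


def half_life(k: float) -> float:
    """First-order half-life ln(2)/k, minutes for k in 1/min."""
    if k <= 0:
        raise DomainError(f"half_life needs k > 0, got {k}")
    return float(np.log(2.0) / k)


def release_plateau(
    params: KineticParams, window: tuple[float, float], n: int = 512
) -> float:
    """Relative variation (max-min)/mean of BA(t) over a time window.

    Small values indicate the controlled-release regime where hydrolysis
    replenishes the acid about as fast as protodeboronation consumes it.
    """
    t_lo, t_hi = window
    if not t_lo < t_hi:
        raise ConfigurationError(f"window must satisfy t_lo < t_hi, got {window}")
    t = np.linspace(t_lo, t_hi, n)
    _, ba, _ = profiles(params, t)
    mean = float(np.mean(ba))
    if mean <= 0:
        raise DomainError("BA(t) is zero over the window; relative variation undefined")
    return float((np.max(ba) - np.min(ba)) / mean)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class KineticFit:
    """Joint pseudo-first-order fit over one or more time courses."""

    k_p: float
    k_h: float | None
    se_k_p: float
    se_k_h: float | None
    rms: float
    rss: float
    n_obs: int
    ambiguous: bool = False  # near-symmetric k_p/k_h solution (ester-only data)
    runs: list[TimeCourse] = field(default_factory=list)

    @property
    def half_life_p(self) -> float:
        return half_life(self.k_p)

    def predict(self, run: TimeCourse) -> np.ndarray:
        ba0, be0 = run.initials()
        p = KineticParams(self.k_p, self.k_h or 0.0, BA0=ba0, BE0=be0)
        be, ba, comb = profiles(p, run.t)
        return ba if run.observable == "BA_only" else comb


def _residuals(log_k: np.ndarray, runs: list[TimeCourse], fit_kh: bool) -> np.ndarray:
    # clip keeps Levenberg-Marquardt trial steps from overflowing exp()
    log_k = np.clip(log_k, -20.0, 6.0)
    k_p = float(np.exp(log_k[0]))
    k_h = float(np.exp(log_k[1])) if fit_kh else 0.0
    out = []
    for run in runs:
        ba0, be0 = run.initials()
        p = KineticParams(k_p, k_h, BA0=max(ba0, 0.0), BE0=max(be0, 0.0))
        be, ba, comb = profiles(p, run.t)
        model = ba if run.observable == "BA_only" else comb
        out.append(model - run.c)
    return np.concatenate(out)


def _slope_init(runs: list[TimeCourse]) -> float:
    """Early-time log-linear decay slope of the acid-only runs (or all runs)."""
    pool = [r for r in runs if r.observable == "BA_only"] or runs
    slopes = []
    for r in pool:
        mask = r.c > 0
        if mask.sum() >= 2:
            s = np.polyfit(r.t[mask], np.log(r.c[mask]), 1)[0]
            if s < 0:
                slopes.append(-s)
    return float(np.median(slopes)) if slopes else 0.1


def fit_pseudo_first_order(
    runs: Sequence[TimeCourse], fit_k_h: bool | None = None
) -> KineticFit:
    """Joint nonlinear least squares for (k_p, k_h) on the concentration scale.

    ``fit_k_h`` defaults to True when any run observes the combined pool
    (which is what identifies the hydrolysis rate).  Multi-start over the
    early-time slope estimate plus log-spaced initializations; the best
    residual sum of squares wins.  When only ester-start data identify the
    pair, the swapped (k_h, k_p) root is probed and near-ties are flagged
    ``ambiguous``.
    """
    runs = list(runs)
    if not runs:
        raise FitError("no time courses given")
    has_ester = any(r.observable == "BA_plus_BE" for r in runs)
    has_acid = any(r.observable == "BA_only" for r in runs)
    if fit_k_h is None:
        fit_k_h = has_ester
    if fit_k_h and not has_ester:
        raise FitError("k_h requested but no BA_plus_BE run identifies it")
    if not has_acid and not has_ester:
        raise FitError("no usable runs")
    if all(np.all(r.c == 0) for r in runs):
        raise FitError("all concentrations are zero; nothing to fit")

    s0 = max(_slope_init(runs), 1e-4)
    starts = [s0] + list(np.logspace(-3, 1, 5))
    best = None
    for kp0 in starts:
        for kh0 in ([kp0, 0.3 * kp0, 3.0 * kp0] if fit_k_h else [1.0]):
            x0 = np.log([kp0, kh0]) if fit_k_h else np.log([kp0, 1.0])
            x0 = x0[: 2 if fit_k_h else 1]
            try:
                sol = least_squares(
                    _residuals, x0, args=(runs, fit_k_h), method="lm", xtol=1e-14,
                )
            except Exception:  # pragma: no cover - LM rarely fails outright
                continue
            rss = float(sol.fun @ sol.fun)
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol)
    if best is None:
        raise FitError("all optimizer starts failed")
    rss, sol = best
    n_obs = sum(len(r.t) for r in runs)
    n_par = 2 if fit_k_h else 1
    dof = max(n_obs - n_par, 1)
    rms = float(np.sqrt(rss / n_obs))

    # asymptotic covariance in log-k space -> delta method to natural units
    J = sol.jac
    try:
        cov = (rss / dof) * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(n_par, np.nan)
    k_p = float(np.exp(sol.x[0]))
    k_h = float(np.exp(sol.x[1])) if fit_k_h else None
    se_k_p = float(k_p * se_log[0])
    se_k_h = float(k_h * se_log[1]) if fit_k_h else None

    ambiguous = False
    if fit_k_h and not has_acid and k_h is not None:
        # with only combined-pool data from a pure-ester start the pair can be
        # nearly exchangeable: probe the swapped root
        swapped = _residuals(np.log([k_h, k_p]), runs, True)
        rss_swap = float(swapped @ swapped)
        if rss_swap <= 1.05 * rss and not np.isclose(k_p, k_h, rtol=1e-3):
            ambiguous = True

    return KineticFit(
        k_p=k_p, k_h=k_h, se_k_p=se_k_p, se_k_h=se_k_h,
        rms=rms, rss=rss, n_obs=n_obs, ambiguous=ambiguous, runs=runs,
    )
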