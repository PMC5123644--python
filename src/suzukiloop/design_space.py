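"""Experimental domain: continuous variables, discrete candidates, conditions, records.

The optimization domain mixes continuous reactor settings (temperature,
residence time, catalyst loading, excess ligand equivalents) with a discrete
roster of precatalyst-ligand candidates.  Continuous settings live in native
units and are rounded to the resolution the instrument can actually deliver;
response-surface code works in coded units on [-1, 1].

Canonical variable names used throughout the package (and in the ledger CSV):

``T_C``            reaction temperature, deg C
``t_min``          residence time, minutes
``loading_molpct`` catalyst loading, mol% Pd relative to the limiting aryl halide
``equiv_excess``   excess ligand equivalents beyond the 1:1 bound in the precatalyst

A campaign may hold some of these fixed (e.g. the ligand-equivalents study runs
at fixed residence time and loading); fixed settings live in
``DesignSpace.fixed`` and are resolved by :meth:`DesignSpace.value`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

TEMPERATURE = "T_C"
TIME = "t_min"
LOADING = "loading_molpct"
EQUIV = "equiv_excess"

#: Objectives the optimizer understands.  ``TON`` is moles of product per mole
#: of catalyst charged (yield / loading fraction); ``per_ligand`` divides by the
#: total ligand charged instead (bound + excess); ``yield`` is the raw fraction.
OBJECTIVES = ("TON", "per_ligand", "yield")

PHASES = ("doe1", "doe2", "refine", "tune")

LEDGER_COLUMNS = (
    "candidate",
    "T_C",
    "t_min",
    "loading_molpct",
    "equiv_excess",
    "yield",
    "response",
    "phase",
    "run_index",
)


@dataclass(frozen=True)
class ContinuousVariable:
    """A continuous reactor setting with an instrument resolution.

    Parameters
    ----------
    name
        Canonical variable name (see module docstring).
    lower, upper
        Inclusive range in native units.
    units
        Human-readable unit label.
    resolution
        Smallest step the instrument can deliver, native units.  All proposed
        settings are rounded onto the grid ``lower + k * resolution``.
    """

    name: str
    lower: float
    upper: float
    units: str
    resolution: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"variable {self.name!r}: lower ({self.lower}) must be < upper ({self.upper})"
            )
        if not (self.resolution > 0 and self.resolution <= self.upper - self.lower):
            raise ConfigurationError(
                f"variable {self.name!r}: resolution must be in (0, upper-lower]"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.upper - self.lower)

    @property
    def center(self) -> float:
        return 0.5 * (self.upper + self.lower)

    def round(self, x: float) -> float:
        """Snap ``x`` onto the instrument grid and clip to the range."""
        k = np.rint((x - self.lower) / self.resolution)
        return float(np.clip(self.lower + k * self.resolution, self.lower, self.upper))

    def scale(self, x: float | np.ndarray) -> float | np.ndarray:
        """Native units -> coded units in [-1, 1]."""
        return 2.0 * (np.asarray(x) - self.lower) / (self.upper - self.lower) - 1.0

    def unscale(self, u: float | np.ndarray) -> float | np.ndarray:
        """Coded units -> native units (no rounding)."""
        return self.lower + (np.asarray(u) + 1.0) * 0.5 * (self.upper - self.lower)


@dataclass(frozen=True)
class DiscreteCandidate:
    """One precatalyst-ligand combination, treated as a yes/no decision."""

    id: str
    scaffold: str = ""
    ligand: str = ""
    active: bool = True

    @classmethod
    def from_id(cls, cand_id: str) -> "DiscreteCandidate":
        """Parse ids of the form ``P1-L4`` into scaffold/ligand parts."""
        parts = cand_id.split("-", 1)
        if len(parts) == 2:
            return cls(id=cand_id, scaffold=parts[0], ligand=parts[1])
        return cls(id=cand_id)


@dataclass(frozen=True)
class ReactionCondition:
    """A single droplet recipe: candidate id + continuous settings (native units)."""

    candidate: str
    x: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", tuple(float(v) for v in self.x))


@dataclass
class ExperimentRecord:
    """One executed droplet experiment.

    ``yield_frac`` is the observed fractional yield (NaN for a failed droplet);
    ``ton`` is yield / loading fraction; ``response`` is the objective value the
    surrogate is fit to.
    """

    condition: ReactionCondition
    yield_frac: float
    ton: float
    response: float
    phase: str
    run_index: int = -1

    @property
    def ok(self) -> bool:
        return np.isfinite(self.yield_frac)


@dataclass
class DesignSpace:
    """Continuous variables + discrete candidate roster (+ fixed settings)."""

    variables: tuple[ContinuousVariable, ...]
    roster: tuple[DiscreteCandidate, ...]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.roster = tuple(self.roster)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate continuous variable names")
        ids = [c.id for c in self.roster]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("candidate ids must be unique within a roster")
        overlap = set(names) & set(self.fixed)
        if overlap:
            raise ConfigurationError(f"fixed settings shadow variables: {sorted(overlap)}")
        self._index = {n: i for i, n in enumerate(names)}
        self._cands = {c.id: c for c in self.roster}

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def p(self) -> int:
        return len(self.variables)

    def var(self, name: str) -> ContinuousVariable:
        try:
            return self.variables[self._index[name]]
        except KeyError:
            raise DomainError(f"unknown continuous variable {name!r}") from None

    def index(self, name: str) -> int:
        if name not in self._index:
            raise DomainError(f"unknown continuous variable {name!r}")
        return self._index[name]

    def candidate(self, cand_id: str) -> DiscreteCandidate:
        try:
            return self._cands[cand_id]
        except KeyError:
            raise DomainError(f"unknown candidate {cand_id!r}") from None

    def active_candidates(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.roster if c.active)

    def value(self, cond: ReactionCondition, name: str, default: float | None = None) -> float:
        """Resolve a named setting from the condition or the fixed settings."""
        if name in self._index:
            return cond.x[self._index[name]]
        if name in self.fixed:
            return self.fixed[name]
        if default is not None:
            return default
        raise DomainError(f"setting {name!r} is neither a variable nor fixed in this space")

    # -- condition construction / validation -----------------------------
    def make_condition(self, candidate: str, **settings: float) -> ReactionCondition:
        self.candidate(candidate)
        x = []
        for v in self.variables:
            if v.name not in settings:
                raise DomainError(f"missing setting for variable {v.name!r}")
            x.append(v.round(settings[v.name]))
        extra = set(settings) - set(self.names)
        if extra:
            raise DomainError(f"unknown settings {sorted(extra)}")
        return ReactionCondition(candidate=candidate, x=tuple(x))

    def round_condition(self, cond: ReactionCondition) -> ReactionCondition:
        x = tuple(v.round(xi) for v, xi in zip(self.variables, cond.x))
        return ReactionCondition(candidate=cond.candidate, x=x)

    def validate_condition(self, cond: ReactionCondition) -> None:
        self.candidate(cond.candidate)
        if len(cond.x) != self.p:
            raise DomainError(
                f"condition has {len(cond.x)} settings, space has {self.p} variables"
            )
        for v, xi in zip(self.variables, cond.x):
            # allow half a resolution step of numerical slack at the bounds
            tol = 0.5 * v.resolution
            if xi < v.lower - tol or xi > v.upper + tol:
                raise DomainError(
                    f"variable {v.name!r}: value {xi} outside [{v.lower}, {v.upper}] {v.units}"
                )


# ---------------------------------------------------------------------------
# coded-unit scaling
# ---------------------------------------------------------------------------

def scale_condition(cond: ReactionCondition, space: DesignSpace) -> np.ndarray:
    """Map a condition's continuous part to coded units in [-1, 1]."""
    space.validate_condition(cond)
    return np.array([v.scale(xi) for v, xi in zip(space.variables, cond.x)])


def unscale_condition(
    u: Sequence[float], candidate: str, space: DesignSpace
) -> ReactionCondition:
    """Map coded units back to a resolution-rounded native condition."""
    if len(u) != space.p:
        raise DomainError(f"coded vector has length {len(u)}, expected {space.p}")
    x = tuple(v.round(v.unscale(ui)) for v, ui in zip(space.variables, u))
    cond = ReactionCondition(candidate=candidate, x=x)
    space.validate_condition(cond)
    return cond


def scale_matrix(x_native: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Vectorized coded-unit scaling for an (n, p) native-unit matrix."""
    x_native = np.asarray(x_native, dtype=float)
    lo = np.array([v.lower for v in space.variables])
    hi = np.array([v.upper for v in space.variables])
    return 2.0 * (x_native - lo) / (hi - lo) - 1.0


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def compute_response(
    yield_frac: float,
    cond: ReactionCondition,
    space: DesignSpace,
    objective: str = "TON",
) -> float:
    """Objective value for one droplet.

    ``TON``        yield / (loading/100)
    ``per_ligand`` yield / ((loading/100) * (1 + excess equivalents)) —
                   moles product per total moles ligand charged
    ``yield``      the yield itself
    """
    if objective not in OBJECTIVES:
        raise ConfigurationError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
    if not 0.0 <= yield_frac <= 1.0:
        raise DomainError(f"yield_frac {yield_frac} outside [0, 1]")
    if objective == "yield":
        return float(yield_frac)
    loading = space.value(cond, LOADING)
    if loading <= 0:
        raise DomainError(f"catalyst loading must be positive, got {loading} mol%")
    loading_frac = loading / 100.0
    if objective == "TON":
        return float(yield_frac / loading_frac)
    equiv = space.value(cond, EQUIV, default=0.0)
    return float(yield_frac / (loading_frac * (1.0 + equiv)))


def make_record(
    cond: ReactionCondition,
    yield_frac: float,
    space: DesignSpace,
    objective: str,
    phase: str,
    run_index: int = -1,
) -> ExperimentRecord:
    """Assemble an :class:`ExperimentRecord`, deriving TON and the objective value."""
    if phase not in PHASES:
        raise ConfigurationError(f"unknown phase {phase!r}")
    if not np.isfinite(yield_frac):  # failed droplet
        return ExperimentRecord(cond, float("nan"), float("nan"), float("nan"), phase, run_index)
    loading = space.value(cond, LOADING, default=float("nan"))
    ton = yield_frac / (loading / 100.0) if loading > 0 else float("nan")
    response = compute_response(yield_frac, cond, space, objective)
    return ExperimentRecord(cond, float(yield_frac), float(ton), response, phase, run_index)


def implied_yield(
    response: float | np.ndarray,
    cond_loading: float | np.ndarray,
    cond_equiv: float | np.ndarray,
    objective: str,
) -> float | np.ndarray:
    """Invert :func:`compute_response`: the yield a response value implies."""
    if objective == "yield":
        return response
    lf = np.asarray(cond_loading) / 100.0
    if objective == "TON":
        return response * lf
    return response * lf * (1.0 + np.asarray(cond_equiv))


def records_to_frame(records: Iterable[ExperimentRecord], space: DesignSpace):
    """Ledger rows as a pandas DataFrame with the fixed column set."""
    import pandas as pd

    rows = []
    for r in records:
        row = {c: float("nan") for c in LEDGER_COLUMNS}
        row["candidate"] = r.condition.candidate
        for name in (TEMPERATURE, TIME, LOADING, EQUIV):
            try:
                row[name] = space.value(r.condition, name)
            except DomainError:
                pass
        row["yield"] = r.yield_frac
        row["response"] = r.response
        row["phase"] = r.phase
        row["run_index"] = r.run_index
        rows.append(row)
    return pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))
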