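"""Randomized two-level factorial initialization of a campaign.

Stage 1 places every continuous setting at a range extreme (coded +/-1) using
columns of a Hadamard matrix, so main-effect columns are exactly balanced and
mutually orthogonal.  Candidates are dealt onto runs in near-equal counts, in
pairs straddling the two temperature levels so each candidate's temperature
slope is identifiable from the start.  Stage 2 reuses the same structure in a
shrunken box around a target center (per candidate or pooled), clipped to the
domain and rounded to instrument resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import hadamard

from .design_space import TEMPERATURE, DesignSpace, ReactionCondition
from .errors import ConfigurationError


@dataclass
class FactorialDesign:
    runs: list[ReactionCondition]
    generator_spec: str
    stage: str  # "doe1" | "doe2"

    def __len__(self) -> int:
        return len(self.runs)


def _two_level_core(n_runs: int, p: int) -> np.ndarray:
    """(n_runs, p) matrix of +/-1, columns balanced and mutually orthogonal.

    Uses columns of a Sylvester Hadamard matrix tiled to ``n_runs`` rows.  The
    base design order is the largest power of two that divides ``n_runs``,
    capped at 2**p — so when the budget allows, the base is the full 2^p
    factorial (pure coordinate columns 2^j) and every corner is visited;
    otherwise the remaining factors ride on interaction columns and the design
    is a regular fraction.
    """
    if n_runs % 4 != 0:
        raise ConfigurationError(f"n_runs must be a multiple of 4, got {n_runs}")
    pow2 = n_runs & -n_runs  # largest power of 2 dividing n_runs
    min_order = 2 ** max(2, int(np.ceil(np.log2(p + 1))))
    if pow2 < min_order:
        raise ConfigurationError(
            f"{p} factors need a {min_order}-run base design; "
            f"n_runs={n_runs} is not a multiple of it"
        )
    order = min(pow2, 2 ** max(p, 2))
    h = hadamard(order)
    m_bits = int(np.log2(order))
    pure = [2 ** j for j in range(m_bits)]
    others = [j for j in range(1, order) if j not in pure]
    cols = (pure + others)[:p]
    return np.tile(h[:, cols], (n_runs // order, 1)).astype(float)


def _deal_candidates(
    core: np.ndarray,
    space: DesignSpace,
    n_runs: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Assign candidates to design rows, balancing the temperature column.

    Rows are grouped by the sign of the (coded) temperature column and paired
    (+, -); candidates are dealt over the pairs deterministically — cyclically
    with a per-block offset, so each candidate sees both temperature levels and
    distinct design rows across replicate tiles.  The seed randomizes the run
    order only: the multiset of runs is seed-invariant.
    Returns the row order (a permutation of the core) and the candidate per run.
    """
    cands = list(space.active_candidates())
    if not cands:
        raise ConfigurationError("no active candidates in roster")
    k = len(cands)

    if TEMPERATURE in space.names:
        t_col = core[:, space.index(TEMPERATURE)]
    else:
        t_col = core[:, 0]
    pos = [i for i in range(n_runs) if t_col[i] > 0]
    neg = [i for i in range(n_runs) if t_col[i] <= 0]
    interleaved: list[int] = []
    assignment: list[str] = []
    for j, (a, b) in enumerate(zip(pos, neg)):
        cand = cands[(j + j // k) % k]
        interleaved.extend((a, b))
        assignment.extend((cand, cand))
    # leftover rows if the column is (pathologically) unbalanced
    for j, i in enumerate(pos[len(neg):] + neg[len(pos):]):
        interleaved.append(i)
        assignment.append(cands[j % k])

    rows = core[interleaved]
    # randomize the execution order jointly
    perm = rng.permutation(n_runs)
    return rows[perm], [assignment[i] for i in perm]


def fractional_factorial(space: DesignSpace, n_runs: int, seed: int) -> FactorialDesign:
    """Stage-1 randomized two-level design over the full continuous ranges.

    Requires ``n_runs`` to be a multiple of 4 and at least twice the number of
    active candidates (so every candidate appears at least twice).
    Deterministic for a given (space, n_runs, seed).
    """
    k = len(space.active_candidates())
    if n_runs < 2 * k:
        raise ConfigurationError(
            f"n_runs={n_runs} < 2 x {k} candidates; every candidate needs >= 2 runs"
        )
    core = _two_level_core(n_runs, space.p)
    rng = np.random.default_rng(seed)
    rows, cands = _deal_candidates(core, space, n_runs, rng)

    runs = []
    for row, cand in zip(rows, cands):
        x = tuple(
            v.round(v.upper if u > 0 else v.lower) for v, u in zip(space.variables, row)
        )
        runs.append(ReactionCondition(candidate=cand, x=x))
    spec = f"2-level/{space.p}f/{n_runs}r/hadamard"
    return FactorialDesign(runs=runs, generator_spec=spec, stage="doe1")


def targeted_factorial(
    space: DesignSpace,
    center: Mapping[str, Sequence[float]] | Sequence[float],
    n_runs: int,
    seed: int,
    shrink: float = 0.5,
) -> FactorialDesign:
    """Stage-2 two-level design in a shrunken box around ``center``.

    ``center`` is either one native-unit vector (pooled) or a mapping
    candidate id -> native-unit vector.  Levels sit at center +/- shrink *
    half-range per variable, clipped to the bounds and rounded to resolution.
    """
    if not 0.0 < shrink <= 1.0:
        raise ConfigurationError(f"shrink must be in (0, 1], got {shrink}")
    k = len(space.active_candidates())
    if n_runs < 2 * k:
        raise ConfigurationError(
            f"n_runs={n_runs} < 2 x {k} candidates; every candidate needs >= 2 runs"
        )
    core = _two_level_core(n_runs, space.p)
    rng = np.random.default_rng(seed)
    rows, cands = _deal_candidates(core, space, n_runs, rng)

    def center_for(cand: str) -> np.ndarray:
        if isinstance(center, Mapping):
            c = np.asarray(center[cand], dtype=float)
        else:
            c = np.asarray(center, dtype=float)
        if c.shape != (space.p,):
            raise ConfigurationError(
                f"center for {cand!r} has shape {c.shape}, expected ({space.p},)"
            )
        return c

    runs = []
    for row, cand in zip(rows, cands):
        c = center_for(cand)
        x = []
        for v, ci, u in zip(space.variables, c, row):
            if not v.lower <= ci <= v.upper:
                raise ConfigurationError(
                    f"center component {v.name}={ci} outside [{v.lower}, {v.upper}]"
                )
            x.append(v.round(ci + u * shrink * v.half_range))
        runs.append(ReactionCondition(candidate=cand, x=tuple(x)))
    spec = f"2-level/{space.p}f/{n_runs}r/hadamard/shrink={shrink}"
    return FactorialDesign(runs=runs, generator_spec=spec, stage="doe2")
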