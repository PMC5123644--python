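"""Feedback loop: constrained optima, G-optimal selection, elimination, campaign.

The campaign maximizes an objective (by default TON) subject to the yield being
at least ``constraint_frac`` (default 0.9) of the *observed* running maximum
yield — an intentionally calibration-free constraint: it needs no product
isolation, only relative peak areas.

Phases, mirroring an automated droplet campaign:

1. ``doe1``   randomized two-level factorial over the full ranges
2. ``doe2``   targeted factorial in a shrunken box around each candidate's best
              feasible result so far
3. ``refine`` loop of fit -> statistical elimination -> G-optimal next
              experiment, until one candidate remains and its predicted-optimum
              uncertainty is small, or the budget runs out
4. ``tune``   one-dimensional catalyst-loading sweep around the winner's
              optimum with whatever budget remains

Experiment selection is G-optimality aimed at the quantity that matters: the
next droplet is run at the predicted constrained optimum whose log-scale
prediction standard error is largest, so uncertainty in the predicted best
result shrinks fastest.  Candidates are eliminated when the upper confidence
bound of their predicted best falls below the best lower confidence bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .design_space import (
    EQUIV,
    LOADING,
    DesignSpace,
    ExperimentRecord,
    ReactionCondition,
    implied_yield,
    make_record,
)
from .doe import fractional_factorial, targeted_factorial
from .errors import ConfigurationError, FitError, PlantError
from .surrogate import SurrogateModel, feature_matrix, fit, make_feature_spec
from .design_space import scale_matrix

logger = logging.getLogger(__name__)

#: plant callback signature: (condition, run_index) -> observed fractional yield
Plant = Callable[[ReactionCondition, int], float]


@dataclass
class CandidateOptimum:
    """Predicted constrained optimum for one candidate."""

    candidate: str
    cond_star: ReactionCondition
    pred_log: float
    se_log: float
    feasible: bool


@dataclass
class CampaignState:
    """Everything a campaign produced."""

    ledger: list[ExperimentRecord] = field(default_factory=list)
    active: tuple[str, ...] = ()
    phase: str = "doe1"
    budget: int = 0
    best_feasible: ExperimentRecord | None = None
    predicted_optimum: CandidateOptimum | None = None
    model: SurrogateModel | None = None
    eliminated: dict[str, int] = field(default_factory=dict)  # candidate -> run index
    converged: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.ledger)


# ---------------------------------------------------------------------------
# continuous search grid
# ---------------------------------------------------------------------------

class ConditionGrid:
    """Dense resolution-rounded grid over the continuous space, with cached
    feature matrices per candidate (the expensive part of repeated optima)."""

    def __init__(self, space: DesignSpace, points_per_dim: int = 21,
                 temp_coding: str = "coded", time_coding: str = "log"):
        axes = []
        for v in space.variables:
            vals = np.unique([v.round(x) for x in np.linspace(v.lower, v.upper, points_per_dim)])
            axes.append(vals)
        self.space = space
        self.axes = axes
        mesh = np.meshgrid(*axes, indexing="ij")
        self.x_native = np.column_stack([m.ravel() for m in mesh])
        self.n = self.x_native.shape[0]
        try:
            self._loading = self.x_native[:, space.index(LOADING)]
        except Exception:
            self._loading = np.full(self.n, space.fixed.get(LOADING, float("nan")))
        try:
            self._equiv = self.x_native[:, space.index(EQUIV)]
        except Exception:
            self._equiv = np.full(self.n, space.fixed.get(EQUIV, 0.0))
        self._spec = make_feature_spec(space, temp_coding, time_coding)
        self._features: dict[int, np.ndarray] = {}

    def step(self, name: str) -> float:
        """Grid step of one variable (native units)."""
        ax = self.axes[self.space.index(name)]
        return float(np.max(np.diff(ax))) if len(ax) > 1 else 0.0

    def features_for(self, cand_idx: int) -> np.ndarray:
        if cand_idx not in self._features:
            self._features[cand_idx] = feature_matrix(
                self.x_native, np.full(self.n, cand_idx), self.space, self._spec
            )
        return self._features[cand_idx]

    def loading(self) -> np.ndarray:
        return self._loading

    def equiv(self) -> np.ndarray:
        return self._equiv


# ---------------------------------------------------------------------------
# constrained optimum / G-optimal selection / elimination
# ---------------------------------------------------------------------------

def constrained_optimum(
    model: SurrogateModel,
    candidate: str,
    space: DesignSpace,
    constraint_frac: float = 0.9,
    y_max: float | None = None,
    objective: str = "TON",
    grid: ConditionGrid | None = None,
    points_per_dim: int = 21,
) -> CandidateOptimum:
    """Grid-search the predicted constrained optimum for one candidate.

    Maximizes the predicted response subject to the implied yield
    (predicted response x loading fraction for TON) being at least
    ``constraint_frac * y_max``, where ``y_max`` is the running maximum
    *observed* yield.  With ``y_max=None`` (empty ledger) the search is
    unconstrained and the result is flagged infeasible-by-default.
    """
    if not 0.0 <= constraint_frac <= 1.0:
        raise ConfigurationError(f"constraint_frac must be in [0, 1], got {constraint_frac}")
    if grid is None:
        grid = ConditionGrid(space, points_per_dim, model.feature_spec.temp_coding,
                             model.feature_spec.time_coding)
    ci = model.feature_spec.candidate_index(candidate)
    F = grid.features_for(ci)
    mean, se = model.predict_features(F)
    resp = np.maximum(0.0, np.exp(mean) - model.eps)

    # restrict the search to grid points the data can actually predict:
    # points outside the identified row space carry arbitrary minimum-norm
    # extrapolations, and points with leverage > 1 sit outside the sampled
    # design region where a quadratic extrapolates without support
    known = model.identified(F, leverage_cap=1.05)
    if not np.any(known):
        known = model.identified(F)
    if not np.any(known):
        known = np.ones(grid.n, dtype=bool)

    def argmax_where(mask: np.ndarray) -> int:
        sub = np.where(mask)[0]
        return int(sub[np.argmax(mean[sub])])

    if y_max is None or constraint_frac == 0.0:
        # empty ledger (no observed yields) -> constraint-free search, flagged
        # infeasible; constraint_frac=0 is a vacuous but satisfied constraint
        idx = argmax_where(known)
        cond = space.round_condition(ReactionCondition(candidate, tuple(grid.x_native[idx])))
        if y_max is None:
            logger.info("constrained_optimum(%s): empty ledger, constraint-free search", candidate)
        return CandidateOptimum(
            candidate, cond, float(mean[idx]), float(se[idx]), y_max is not None
        )

    y_implied = implied_yield(resp, grid.loading(), grid.equiv(), objective)
    feas = (np.asarray(y_implied) >= constraint_frac * y_max) & known
    if np.any(feas):
        idx = argmax_where(feas)
        feasible = True
    else:
        idx = argmax_where(known)
        feasible = False
    cond = ReactionCondition(candidate, tuple(grid.x_native[idx]))
    return CandidateOptimum(
        candidate, space.round_condition(cond), float(mean[idx]), float(se[idx]), feasible
    )


def candidate_optima(
    model: SurrogateModel,
    active: Sequence[str],
    space: DesignSpace,
    constraint_frac: float,
    y_max: float | None,
    objective: str,
    grid: ConditionGrid | None = None,
) -> list[CandidateOptimum]:
    return [
        constrained_optimum(model, c, space, constraint_frac, y_max, objective, grid)
        for c in active
    ]


def g_optimal_next(
    model: SurrogateModel,
    active: Sequence[str],
    space: DesignSpace,
    constraint_frac: float = 0.9,
    y_max: float | None = None,
    objective: str = "TON",
    grid: ConditionGrid | None = None,
    rng: np.random.Generator | None = None,
) -> ReactionCondition:
    """Next experiment: the most uncertain predicted candidate optimum.

    Ties on the prediction standard error break toward the higher predicted
    response, then by a seeded random draw.
    """
    if not active:
        raise ConfigurationError("no active candidates")
    opts = candidate_optima(model, active, space, constraint_frac, y_max, objective, grid)
    se = np.array([o.se_log for o in opts])
    pred = np.array([o.pred_log for o in opts])
    if np.all(se == 0.0):
        logger.info("all candidate optima have zero prediction SE; picking highest prediction")
        return opts[int(np.argmax(pred))].cond_star
    best_se = se.max()
    tied = np.where(np.isclose(se, best_se, rtol=0.0, atol=1e-12))[0]
    if len(tied) > 1:
        best_pred = pred[tied].max()
        tied = tied[np.isclose(pred[tied], best_pred, rtol=0.0, atol=1e-12)]
    if len(tied) > 1:
        rng = rng if rng is not None else np.random.default_rng(0)
        choice = int(tied[rng.integers(len(tied))])
    else:
        choice = int(tied[0])
    return opts[choice].cond_star


def eliminate(
    model: SurrogateModel,
    active: Sequence[str],
    space: DesignSpace,
    alpha: float = 0.05,
    constraint_frac: float = 0.9,
    y_max: float | None = None,
    objective: str = "TON",
    run_counts: Mapping[str, int] | None = None,
    n_min: int = 3,
    grid: ConditionGrid | None = None,
) -> tuple[str, ...]:
    """Drop candidates whose predicted best is statistically dominated.

    Candidate k is eliminated when ``UCB_k < LCB_best`` with t-intervals at
    level ``alpha`` on the model's residual degrees of freedom, where both
    bounds are evaluated at each candidate's own predicted constrained optimum.
    The benchmark ``LCB_best`` comes from candidates whose optimum satisfies
    the yield constraint (an infeasible fallback optimum is not a result worth
    defending).  The benchmark holder is never eliminated, nor is a candidate
    with fewer than ``n_min`` successful runs, and at least one candidate
    always survives.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if len(active) <= 1:
        return tuple(active)
    opts = candidate_optima(model, active, space, constraint_frac, y_max, objective, grid)
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, model.dof))
    lcb = np.array([o.pred_log - tcrit * o.se_log for o in opts])
    ucb = np.array([o.pred_log + tcrit * o.se_log for o in opts])
    feas = np.array([o.feasible for o in opts])
    if np.any(feas):
        lcb_pool = np.where(feas, lcb, -np.inf)
    else:
        lcb_pool = lcb
    best = int(np.argmax(lcb_pool))
    keep = []
    for i, cand in enumerate(active):
        enough = run_counts is None or run_counts.get(cand, 0) >= n_min
        if i == best or not enough or ucb[i] >= lcb[best]:
            keep.append(cand)
    return tuple(keep) if keep else (active[best],)


def best_feasible(
    ledger: Sequence[ExperimentRecord], constraint_frac: float = 0.9
) -> ExperimentRecord:
    """Best-response record among those meeting the relative yield floor.

    Feasible means yield >= constraint_frac * max observed yield; the maximum
    yield record is always feasible, so the set is never empty.  Ties break to
    the earliest run.
    """
    good = [r for r in ledger if r.ok]
    if not good:
        raise ConfigurationError("ledger holds no successful experiments")
    y_max = max(r.yield_frac for r in good)
    feas = [r for r in good if r.yield_frac >= constraint_frac * y_max]
    return max(feas, key=lambda r: (r.response, -r.run_index))


# ---------------------------------------------------------------------------
# campaign driver
# ---------------------------------------------------------------------------

def _run_counts(ledger: Iterable[ExperimentRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in ledger:
        if r.ok:
            counts[r.condition.candidate] = counts.get(r.condition.candidate, 0) + 1
    return counts


def _observed_y_max(ledger: Sequence[ExperimentRecord]) -> float | None:
    """Running maximum of the condition-averaged observed yields.

    Replicates of the same condition are averaged before taking the maximum:
    the raw single-droplet maximum over a campaign is biased upward by about
    two noise standard deviations, which would silently raise the relative
    yield floor and push the constrained optimum to higher loading.
    """
    sums: dict[tuple, list[float]] = {}
    for r in ledger:
        if r.ok:
            key = (r.condition.candidate, r.condition.x)
            s = sums.setdefault(key, [0.0, 0.0])
            s[0] += r.yield_frac
            s[1] += 1.0
    if not sums:
        return None
    return max(s[0] / s[1] for s in sums.values())


class _Executor:
    """Runs droplets against the plant, with budget accounting and retries."""

    def __init__(self, plant: Plant, space: DesignSpace, objective: str, budget: int,
                 max_retries: int = 2):
        self.plant = plant
        self.space = space
        self.objective = objective
        self.budget = budget
        self.max_retries = max_retries
        self.ledger: list[ExperimentRecord] = []

    @property
    def remaining(self) -> int:
        return self.budget - len(self.ledger)

    def run(self, cond: ReactionCondition, phase: str) -> ExperimentRecord | None:
        """Execute one condition; on plant failure, re-propose up to max_retries.
        Every attempt consumes budget (a droplet was spent either way)."""
        attempts = 0
        while self.remaining > 0:
            idx = len(self.ledger)
            try:
                y = float(self.plant(cond, idx))
            except PlantError as exc:
                logger.warning("droplet %d failed (%s); attempt %d", idx, exc, attempts + 1)
                rec = make_record(cond, float("nan"), self.space, self.objective, phase, idx)
                self.ledger.append(rec)
                attempts += 1
                if attempts > self.max_retries:
                    return None
                continue
            y = float(np.clip(y, 0.0, 1.0))
            rec = make_record(cond, y, self.space, self.objective, phase, idx)
            self.ledger.append(rec)
            logger.info(
                "run %d [%s] %s %s -> yield %.3f response %.2f",
                idx, phase, cond.candidate, cond.x, y, rec.response,
            )
            return rec
        return None


def run_campaign(plant: Plant, config) -> CampaignState:
    """Execute a full closed-loop campaign against a plant callback.

    ``config`` is a :class:`suzukiloop.io_cli.CampaignConfig` (or anything with
    the same attributes).  ``plant`` maps (condition, run_index) to an observed
    fractional yield and may raise :class:`PlantError` for a failed droplet.
    All stochastic choices derive from ``config.seed`` via independent
    substreams, so a repeated run is byte-identical.
    """
    space: DesignSpace = config.space
    objective: str = config.objective
    frac: float = config.constraint_frac
    budget: int = config.budget
    if budget < config.stage1_runs:
        raise ConfigurationError(
            f"budget {budget} < stage-1 size {config.stage1_runs}"
        )
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4)  # doe1, doe2, refine ties, (spare)
    tie_rng = np.random.default_rng(int(seeds[2]))

    grid = ConditionGrid(space, config.grid_points, config.temp_coding, config.time_coding)
    ex = _Executor(plant, space, objective, budget)
    state = CampaignState(ledger=ex.ledger, active=space.active_candidates(), budget=budget)
    K = len(state.active)

    # -- stage 1: full-range factorial -----------------------------------
    design1 = fractional_factorial(space, config.stage1_runs, int(seeds[0]))
    for cond in design1.runs:
        if ex.remaining <= 0:
            break
        ex.run(cond, "doe1")

    # -- stage 2: targeted factorial --------------------------------------
    n2 = config.stage2_runs if config.stage2_runs else 4 * int(np.ceil(2 * K / 4))
    n2 = min(n2, 4 * (ex.remaining // 4))
    if n2 >= max(4, 2 * K):
        state.phase = "doe2"
        centers = _stage2_centers(ex.ledger, state.active, space, frac)
        design2 = targeted_factorial(space, centers, n2, int(seeds[1]), shrink=config.shrink)
        for cond in design2.runs:
            if ex.remaining <= 0:
                break
            ex.run(cond, "doe2")

    # -- refine loop: G-optimal challenges + elimination -------------------
    # a slice of the budget is held back so the winner-refinement and
    # loading-tuning stages always run (the staged-campaign structure)
    state.phase = "refine"
    # reserve: Y_max pinning + one full local composite design + verification
    # replicates + the loading line search — the endgame must not be starved
    p_nl = space.p - (1 if LOADING in space.names else 0)
    winner_reserve = (
        2 + (2 ** space.p + 2 * space.p + 2) + 6 * p_nl
        + (10 if LOADING in space.names else 0)
    )
    while ex.remaining > max(winner_reserve, 1) and len(state.active) > 1:
        try:
            model = fit(ex.ledger, space, config.temp_coding, time_coding=config.time_coding)
        except FitError as exc:
            logger.warning("fit failed (%s); stopping refinement", exc)
            break
        state.model = model
        y_max = _observed_y_max(ex.ledger)
        counts = _run_counts(ex.ledger)
        new_active = eliminate(
            model, state.active, space, config.alpha, frac, y_max, objective,
            run_counts=counts, n_min=config.n_min_elim, grid=grid,
        )
        for cand in state.active:
            if cand not in new_active:
                state.eliminated[cand] = len(ex.ledger)
        state.active = new_active
        if len(state.active) == 1:
            break
        cond = g_optimal_next(model, state.active, space, frac, y_max, objective, grid, tie_rng)
        if ex.run(cond, "refine") is None:
            break

    # -- winner endgame: local refinement, loading tuning, verification -----
    verified: CandidateOptimum | None = None
    if state.active:
        verified = _endgame(ex, state, space, config, grid)

    # -- final fit and bookkeeping ----------------------------------------
    try:
        state.model = fit(ex.ledger, space, config.temp_coding, time_coding=config.time_coding)
    except FitError:
        pass
    y_max = _observed_y_max(ex.ledger)
    if verified is not None:
        state.predicted_optimum = verified
    elif state.model is not None and state.active:
        opts = candidate_optima(state.model, state.active, space, frac, y_max, objective, grid)
        ranked = _rank_optima(opts)
        # report the winner's optimum from the local refit when one exists
        local = _local_fit(ex.ledger, ranked.candidate, space, config)
        if local is not None:
            lo = constrained_optimum(local, ranked.candidate, space, frac, y_max,
                                     objective, grid)
            if lo.feasible or not ranked.feasible:
                ranked = lo
        state.predicted_optimum = ranked
    if any(r.ok for r in ex.ledger):
        state.best_feasible = best_feasible(ex.ledger, frac)
    return state


def _ccd_conditions(
    space: DesignSpace, candidate: str, center_x: np.ndarray, shrink: float
) -> list[ReactionCondition]:
    """Small central-composite design around a native-unit center.

    Two-level corners at center +/- shrink * half-range, one center point and
    two axial points per variable at the same radius — enough to identify a
    full local quadratic.  Clipped to bounds, rounded to resolution, deduped.
    """
    from itertools import product

    p = space.p
    if p <= 4:
        corners = np.array(list(product((-1.0, 1.0), repeat=p)))
    else:
        from .doe import _two_level_core

        corners = _two_level_core(8 * int(np.ceil(2 * p / 8)), p)
    rows = [np.zeros(p)]
    rows.extend(corners)
    for j in range(p):
        for sgn in (-1.0, 1.0):
            ax = np.zeros(p)
            ax[j] = sgn
            rows.append(ax)
    conds = []
    seen = set()
    for row in rows:
        x = tuple(
            v.round(c + u * shrink * v.half_range)
            for v, c, u in zip(space.variables, center_x, row)
        )
        if x not in seen:
            seen.add(x)
            conds.append(ReactionCondition(candidate, x))
    return conds


def _endgame(
    ex: "_Executor",
    state: CampaignState,
    space: DesignSpace,
    config,
    grid: ConditionGrid,
) -> CandidateOptimum | None:
    """Winner endgame: local refinement, verification, then loading tuning.

    1. Pin the observed maximum yield (the relative floor needs it).
    2. Rounds of {central-composite design around the incumbent -> local
       quadratic refit -> challenge the predicted constrained optimum},
       re-centering on the model optimum so boundary-directed optima walk to
       the domain edge.
    3. Verification: replicate the predicted optimum and its one-grid-step
       neighbors in the non-loading dimensions and keep the best *observed*
       feasible point — settles temperature/time by data, not extrapolation.
    4. A directed loading line-search at the verified settings down to the
       feasibility boundary, with the final loading read off a local linear
       regression of observed yield on loading.
    """
    frac, objective = config.constraint_frac, config.objective
    if state.model is None:
        try:
            state.model = fit(ex.ledger, space, config.temp_coding,
                              time_coding=config.time_coding)
        except FitError:
            return None
    if len(state.active) == 1:
        winner = state.active[0]
    else:
        # budget deadline hit before elimination finished: refine the current
        # front-runner (feasible-first ranking); the rest stay active
        y0 = _observed_y_max(ex.ledger)
        opts = candidate_optima(state.model, state.active, space, frac, y0, objective, grid)
        winner = _rank_optima(opts).candidate

    # the relative yield floor is only as good as the best yield actually
    # observed, and TON-chasing never samples the high-yield region on its own
    _pin_y_max(ex, state, winner, space, config, grid)

    has_loading = LOADING in space.names
    tune_floor = 10 if has_loading else 0
    verify_floor = tune_floor + 3 * (2 * (space.p - (1 if has_loading else 0)))
    local: SurrogateModel | None = None
    center = _winner_center(ex.ledger, winner, space, frac)
    for _ in range(config.local_rounds):
        if ex.remaining <= verify_floor + 4:
            break
        for cond in _ccd_conditions(space, winner, center, config.local_shrink):
            if ex.remaining <= verify_floor:
                break
            ex.run(cond, "refine")
        local = _local_fit(ex.ledger, winner, space, config, center=center) or local
        if local is None:
            break
        y_max = _observed_y_max(ex.ledger)
        opt = constrained_optimum(local, winner, space, frac, y_max, objective, grid)
        if ex.remaining > verify_floor:
            ex.run(opt.cond_star, "refine")
        # re-center on the model's optimum (noise-averaged), not the luckiest
        # single observation
        new_center = np.asarray(opt.cond_star.x)
        moved = np.any(
            np.abs(
                scale_matrix(new_center[None, :], space)
                - scale_matrix(np.asarray(center)[None, :], space)
            )
            > config.local_shrink
        )
        center = new_center
        if not moved and opt.se_log < config.se_tol:
            state.converged = True
            break

    model = local if local is not None else state.model
    y_max = _observed_y_max(ex.ledger)
    opt = constrained_optimum(model, winner, space, frac, y_max, objective, grid)
    skip = (space.index(LOADING),) if has_loading else ()
    opt = _snap_to_bounds(opt, model, space, grid, frac, y_max, objective, skip)

    # settle the non-loading coordinates by replicated observation
    opt = _verify_optimum(ex, winner, opt, model, space, config, grid,
                          skip_dims=skip, budget_floor=tune_floor)

    if has_loading and ex.remaining > 0:
        state.phase = "tune"
        _tune_loading(ex, opt, space, grid, config, max_runs=ex.remaining)
        li = space.index(LOADING)
        v = space.variables[li]
        loading_star = _crossing_loading(ex.ledger, winner, opt, space, frac)
        # polish: replicate the crossing and its neighbors with any leftover
        # budget, then re-read the crossing off the pooled data
        while loading_star is not None and ex.remaining > 0:
            targets = [
                v.round(loading_star + k * v.resolution) for k in (-1, 0, 1)
            ]
            progressed = False
            for lv in dict.fromkeys(targets):
                x = list(opt.cond_star.x)
                x[li] = lv
                c = ReactionCondition(winner, tuple(x))
                if ex.remaining > 0 and len(_matching_obs(ex.ledger, winner, c.x)) < 6:
                    ex.run(c, "tune")
                    progressed = True
            new_star = _crossing_loading(ex.ledger, winner, opt, space, frac)
            if new_star is not None:
                loading_star = new_star
            if not progressed:
                break
        if loading_star is not None:
            x = list(opt.cond_star.x)
            x[li] = loading_star
            cond = ReactionCondition(winner, tuple(x))
            model2 = _local_fit(ex.ledger, winner, space, config,
                                center=np.asarray(cond.x)) or model
            pred_log, se_log = model2.predict(cond)
            opt = CandidateOptimum(winner, cond, pred_log, se_log, True)
    return opt


def _crossing_loading(ledger, winner: str, opt: CandidateOptimum,
                      space: DesignSpace, frac: float) -> float | None:
    """Loading where observed yield crosses the relative floor, from a linear
    regression of the droplets run at the optimum's other settings.

    The TON optimum sits at the smallest loading that still meets the yield
    floor; reading the crossing off pooled observations averages the
    measurement noise instead of trusting one droplet either side.
    """
    li = space.index(LOADING)
    v = space.variables[li]
    others = [i for i in range(space.p) if i != li]
    obs = [
        r for r in ledger
        if r.ok and r.condition.candidate == winner
        and all(abs(r.condition.x[i] - opt.cond_star.x[i]) <= 1e-9 for i in others)
    ]
    loadings = np.array([r.condition.x[li] for r in obs])
    yields = np.array([r.yield_frac for r in obs])
    if len(np.unique(loadings)) < 3:
        return None
    y_max = _observed_y_max(ledger)
    if y_max is None:
        return None
    floor = frac * y_max
    lo_obs, hi_obs = float(np.min(loadings)), float(np.max(loadings))

    def regress(mask: np.ndarray) -> float | None:
        if len(np.unique(loadings[mask])) < 3:
            return None
        b, a = np.polyfit(loadings[mask], yields[mask], 1)
        if b <= 1e-6:
            return None
        return (floor - a) / b

    crossing = regress(np.ones(len(loadings), dtype=bool))
    if crossing is None:
        # yield flat in loading over the sweep: everything sampled is feasible,
        # take the smallest loading sampled
        lo = float(np.min(loadings))
        return v.round(lo) if np.mean(yields[loadings == np.min(loadings)]) >= floor else None
    # second pass: refit on the points near the provisional crossing so the
    # local slope (not the whole concave sweep) sets the estimate
    near = np.abs(loadings - crossing) <= 3.5 * v.resolution
    refined = regress(near)
    if refined is not None:
        crossing = refined
    crossing = float(np.clip(crossing, lo_obs - v.resolution, hi_obs))
    return v.round(max(crossing, v.lower))


def _snap_to_bounds(
    opt: CandidateOptimum,
    model: SurrogateModel,
    space: DesignSpace,
    grid: ConditionGrid,
    frac: float,
    y_max: float | None,
    objective: str,
    skip_dims: tuple[int, ...] = (),
) -> CandidateOptimum:
    """Prefer a domain bound when the optimum is one step away and the bound
    predicts as well (within one SE) without violating the yield floor.

    On a flat saturating surface the fitted vertex wobbles one step inside the
    boundary from noise alone; a true interior optimum has enough curvature
    that the bound predicts clearly worse and is never taken.
    """
    if y_max is None:
        return opt
    x = list(opt.cond_star.x)
    mean0, se0 = model.predict(opt.cond_star)
    changed = False
    for i, v in enumerate(space.variables):
        if i in skip_dims:
            continue
        stp = grid.step(v.name)
        for bound in (v.lower, v.upper):
            if 0.0 < abs(x[i] - bound) <= stp + 1e-9:
                trial = list(x)
                trial[i] = bound
                cond = ReactionCondition(opt.candidate, tuple(trial))
                mean_b, se_b = model.predict(cond)
                resp = max(0.0, float(np.exp(mean_b)) - model.eps)
                loading = space.value(cond, LOADING, default=float("nan"))
                equiv = space.value(cond, EQUIV, default=0.0)
                y_impl = implied_yield(resp, loading, equiv, objective)
                if mean_b >= mean0 - se0 and (
                    objective == "yield" or not np.isfinite(loading)
                    or y_impl >= frac * y_max
                ):
                    x = trial
                    changed = True
    if not changed:
        return opt
    cond = ReactionCondition(opt.candidate, tuple(x))
    mean, se = model.predict(cond)
    return CandidateOptimum(opt.candidate, cond, float(mean), float(se), opt.feasible)


def _anchor_feasible(ledger, winner: str, frac: float) -> ReactionCondition | None:
    """Best-response feasible observed condition of one candidate, or None."""
    good = [r for r in ledger if r.ok]
    mine = [r for r in good if r.condition.candidate == winner]
    if not mine:
        return None
    y_max = max(r.yield_frac for r in good)
    feas = [r for r in mine if r.yield_frac >= frac * y_max]
    if not feas:
        return None
    return max(feas, key=lambda r: (r.response, -r.run_index)).condition


def _matching_obs(ledger, winner: str, x: tuple) -> list[ExperimentRecord]:
    out = []
    for r in ledger:
        if r.ok and r.condition.candidate == winner and len(r.condition.x) == len(x):
            if all(abs(a - b) <= 1e-9 for a, b in zip(r.condition.x, x)):
                out.append(r)
    return out


def _verify_optimum(
    ex: "_Executor",
    winner: str,
    opt: CandidateOptimum,
    model: SurrogateModel,
    space: DesignSpace,
    config,
    grid: ConditionGrid,
    skip_dims: tuple[int, ...] = (),
    budget_floor: int = 0,
) -> CandidateOptimum:
    """Replicate the predicted optimum and its one-grid-step neighbors; return
    the best observed feasible point (pooling every droplet ever run there).

    ``skip_dims`` lists variable indices not varied here (loading has its own
    line search).  Up to two hill-climb moves: if a neighbor beats the
    incumbent on pooled mean response, verification re-centers on it.
    """
    frac = config.constraint_frac
    base = opt.cond_star
    for _move in range(2):
        conds = [base]
        for i, v in enumerate(space.variables):
            if i in skip_dims:
                continue
            stp = grid.step(v.name)
            if stp <= 0:
                continue
            for sgn in (-1.0, 1.0):
                x = list(base.x)
                x[i] = v.round(x[i] + sgn * stp)
                c = ReactionCondition(winner, tuple(x))
                if not any(
                    all(abs(a - b) <= 1e-9 for a, b in zip(c.x, d.x)) for d in conds
                ):
                    conds.append(c)
        # round-robin replication until each point has >= 3 observations
        while ex.remaining > budget_floor:
            need = [
                c for c in conds if len(_matching_obs(ex.ledger, winner, c.x)) < 3
            ]
            if not need:
                break
            for c in need:
                if ex.remaining <= budget_floor:
                    break
                ex.run(c, "tune")
        y_max = _observed_y_max(ex.ledger)
        floor = frac * (y_max or 0.0)
        sigma_rel = float(np.sqrt(max(model.sigma2, 1e-6)))  # log-scale ~ relative sd
        stats_by_cond = []
        for c in conds:
            obs = _matching_obs(ex.ledger, winner, c.x)
            if not obs:
                continue
            m_yield = float(np.mean([r.yield_frac for r in obs]))
            m_resp = float(np.mean([r.response for r in obs]))
            se_resp = m_resp * sigma_rel / np.sqrt(len(obs))
            se_yield = m_yield * sigma_rel / np.sqrt(len(obs))
            stats_by_cond.append((c, m_resp, se_resp, m_yield, se_yield))
        if not stats_by_cond:
            break
        base_stat = next(
            (s for s in stats_by_cond
             if all(abs(a - b) <= 1e-9 for a, b in zip(s[0].x, base.x))),
            None,
        )
        feas_stats = [s for s in stats_by_cond if s[3] >= floor]
        if not feas_stats:
            # every point here violates the floor: the model led verification
            # into a bad basin; restart from the best observed feasible droplet
            anchor = _anchor_feasible(ex.ledger, winner, frac)
            if anchor is not None and not all(
                abs(a - b) <= 1e-9 for a, b in zip(anchor.x, base.x)
            ):
                base = anchor
                continue
            feas_stats = [max(stats_by_cond, key=lambda s: s[3])]
        best = max(feas_stats, key=lambda s: s[1])
        # move off the model's point only when the observed gain is
        # significant (or the model's point clearly violates the floor):
        # on a flat ridge the replicate means are coin flips
        if base_stat is not None:
            gain = best[1] - base_stat[1]
            gate = 1.64 * float(np.hypot(best[2], base_stat[2]))
            base_ok = base_stat[3] >= floor - 1.64 * base_stat[4]
            if gain <= gate and base_ok:
                break
        if all(abs(a - b) <= 1e-9 for a, b in zip(best[0].x, base.x)):
            break
        base = best[0]
        if ex.remaining <= budget_floor:
            break
    pred_log, se_log = model.predict(base)
    return CandidateOptimum(winner, base, pred_log, se_log, True)


def _pin_y_max(ex, state, winner: str, space: DesignSpace, config, grid) -> None:
    """Run the winner at its predicted maximum-yield condition (twice).

    Executed once per campaign: anchors the observed Y_max near the plant's
    achievable maximum so the yield floor is meaningful.
    """
    if getattr(state, "_y_max_pinned", False) or state.model is None:
        return
    try:
        ci = state.model.feature_spec.candidate_index(winner)
    except Exception:
        return
    F = grid.features_for(ci)
    mean, _ = state.model.predict_features(F)
    resp = np.maximum(0.0, np.exp(mean) - state.model.eps)
    y_pred = np.asarray(
        implied_yield(resp, grid.loading(), grid.equiv(), config.objective)
    )
    known = state.model.identified(F)
    if np.any(known):
        y_pred = np.where(known, y_pred, -np.inf)
    idx = int(np.argmax(y_pred))
    cond = space.round_condition(ReactionCondition(winner, tuple(grid.x_native[idx])))
    for _ in range(2):
        if ex.remaining <= 0:
            return
        ex.run(cond, "refine")
    state._y_max_pinned = True


def _winner_center(ledger, candidate, space, frac) -> np.ndarray:
    good = [r for r in ledger if r.ok]
    mine = [r for r in good if r.condition.candidate == candidate]
    if not mine:
        return np.array([v.center for v in space.variables])
    y_max = max(r.yield_frac for r in good)
    feas = [r for r in mine if r.yield_frac >= frac * y_max]
    best = max(feas or mine, key=lambda r: (r.response, -r.run_index))
    return np.asarray(best.condition.x)


def _local_fit(
    ledger: Sequence[ExperimentRecord],
    candidate: str,
    space: DesignSpace,
    config,
    radius: float | None = None,
    center: np.ndarray | None = None,
) -> SurrogateModel | None:
    """Quadratic refit on the records near the incumbent best (trust region).

    Once one candidate remains, the global surface's job is done; standard
    response-surface practice is a local canonical fit around the incumbent
    optimum, which removes the bias a full-range quadratic accumulates from
    far-away corners.  Centered on the candidate's best feasible observed
    condition (or an explicit native-unit ``center``), with a coded L-inf
    radius slightly over the local design box.
    Returns None when too few local records exist to say anything.
    """
    if radius is None:
        radius = getattr(config, "local_radius", 0.35)
    good = [r for r in ledger if r.ok]
    mine = [r for r in good if r.condition.candidate == candidate]
    if not mine:
        return None
    if center is None:
        y_max = max(r.yield_frac for r in good)
        feas = [r for r in mine if r.yield_frac >= config.constraint_frac * y_max]
        center_rec = max(feas or mine, key=lambda r: (r.response, -r.run_index))
        center = np.asarray(center_rec.condition.x)
    u0 = scale_matrix(np.asarray(center)[None, :], space)[0]
    u_all = scale_matrix(np.array([r.condition.x for r in mine]), space)
    near = np.all(np.abs(u_all - u0) <= radius + 1e-12, axis=1)
    local = [r for r, m in zip(mine, near) if m]
    p = space.p
    if len(local) < (p + 1) * (p + 2) // 2 + 2:
        return None
    try:
        return fit(local, space, config.temp_coding, time_coding=config.time_coding)
    except FitError:
        return None


def _stage2_centers(
    ledger: Sequence[ExperimentRecord],
    active: Sequence[str],
    space: DesignSpace,
    frac: float,
) -> dict[str, np.ndarray]:
    """Per-candidate stage-2 centers: the candidate's best feasible observed
    condition, or the pooled best feasible condition when it has none."""
    good = [r for r in ledger if r.ok]
    pooled = best_feasible(ledger, frac).condition if good else None
    y_max = max((r.yield_frac for r in good), default=0.0)
    centers: dict[str, np.ndarray] = {}
    for cand in active:
        mine = [
            r for r in good
            if r.condition.candidate == cand and r.yield_frac >= frac * y_max
        ]
        if mine:
            best = max(mine, key=lambda r: (r.response, -r.run_index))
            centers[cand] = np.asarray(best.condition.x)
        elif pooled is not None:
            centers[cand] = np.asarray(pooled.x)
        else:
            centers[cand] = np.array([v.center for v in space.variables])
    return centers


def _rank_optima(opts: Sequence[CandidateOptimum]) -> CandidateOptimum:
    """Best candidate optimum: feasible ones outrank infeasible fallbacks."""
    return max(opts, key=lambda o: (o.feasible, o.pred_log))


def _current_winner(state, ledger, space, frac, objective, grid, config):
    if state.model is None or not state.active:
        return None
    y_max = _observed_y_max(ledger)
    opts = candidate_optima(state.model, state.active, space, frac, y_max, objective, grid)
    ranked = _rank_optima(opts)
    local = _local_fit(ledger, ranked.candidate, space, config)
    if local is not None:
        lo = constrained_optimum(local, ranked.candidate, space, frac, y_max, objective, grid)
        if lo.feasible or not ranked.feasible:
            ranked = lo
    return ranked


def _tune_loading(ex: _Executor, winner: CandidateOptimum, space: DesignSpace,
                  grid: ConditionGrid, config, max_runs: int | None = None) -> None:
    """Tune catalyst loading at the winner's optimal remaining settings.

    TON rises as loading falls until the yield floor bites, so the sweep is a
    directed line search: step the loading down one resolution step at a time
    while the observed yield stays feasible (with one step of hysteresis below
    the floor before giving up), then spend any leftover droplets replicating
    the two loadings that straddle the feasibility boundary.
    """
    v = space.var(LOADING)
    li = space.index(LOADING)
    budget = max_runs if max_runs is not None else ex.remaining
    used = 0

    def run_at(val: float) -> ExperimentRecord | None:
        nonlocal used
        x = list(winner.cond_star.x)
        x[li] = v.round(val)
        used += 1
        return ex.run(ReactionCondition(winner.candidate, tuple(x)), "tune")

    frac = config.constraint_frac
    current = winner.cond_star.x[li]
    last_feasible = None
    first_infeasible = None
    misses = 0
    while ex.remaining > 0 and used < budget and current >= v.lower - 1e-9:
        rec = run_at(current)
        if rec is None:
            return
        y_max = _observed_y_max(ex.ledger)
        if rec.yield_frac >= frac * y_max:
            last_feasible = current
            misses = 0
        else:
            first_infeasible = current
            misses += 1
            if misses >= 2:  # two consecutive infeasible steps: stop descending
                break
        if current <= v.lower + 1e-9:
            break
        current = v.round(current - v.resolution)
    # replicate the straddle pair to sharpen the crossing estimate
    straddle = [x for x in (last_feasible, first_infeasible) if x is not None]
    i = 0
    while ex.remaining > 0 and used < budget and straddle and i < 2 * len(straddle):
        if run_at(straddle[i % len(straddle)]) is None:
            return
        i += 1
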