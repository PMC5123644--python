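# Methods

`suzukiloop` implements model-based closed-loop optimization of
Suzuki–Miyaura cross-couplings over a mixed domain: a discrete roster of
precatalyst–ligand candidates and continuous reactor settings (temperature,
residence time, catalyst loading, and optionally excess ligand equivalents).
This note records the models, the numerical choices, and the limits of what
the in-silico tests demonstrate.

## Objective and constraint

The default objective is turnover number, TON = yield / (loading/100),
maximized subject to the yield being at least a fraction *f* (default 0.9) of
the maximum yield observed so far. The constraint is deliberately relative:
it needs no product calibration, only relative detector response, so a
campaign can start before any product has been isolated. The `per_ligand`
objective divides instead by the total ligand charged,
yield / ((loading/100)·(1 + excess equivalents)), for campaigns that weigh
ligand cost. Because the floor is an *observed* quantity, the package
estimates it as the running maximum of condition-averaged yields: averaging
replicates first removes the ≈ +2σ upward bias that the raw single-droplet
maximum accumulates over a ~100-droplet campaign, a bias that would otherwise
shift the constrained loading optimum upward by several resolution steps.

## Response surface

The surrogate is ordinary least squares for z = ln(response + ε), ε = 0.01,
on a shared-structure design matrix: per-candidate intercepts
("pre-exponential offsets" — candidate effects are multiplicative on the
response scale), per-candidate temperature slopes, and *shared* linear,
pairwise-interaction, and quadratic terms in the coded continuous variables.
There is no global intercept and no shared linear temperature column; both
would be collinear with the candidate blocks. Consequence: the predicted
log-response difference between two candidates at fixed settings is affine in
the temperature regressor — the model can reorder candidates with
temperature but shares all other curvature, which is what lets a handful of
runs per candidate support elimination decisions.

Codings. Variables are scaled to [−1, 1]. Temperature may enter the
candidate-specific terms either as plain coded T (default) or as a rescaled
−1000/T(K) ("arrhenius"). Residence time is log-coded by default
(`time_coding="log"`): droplet residence times span a decade, the underlying
kinetics are (pseudo) first order, and a quadratic in plain t badly distorts
saturating yield curves — in closed-loop tests it displaced a true boundary
optimum at t = 10 min to ≈ 7.8 min, while the log coding recovers the
boundary.

Fitting uses a single SVD, which supplies the minimum-norm solution, the
coefficient covariance σ²(XᵀX)⁺, the rank, and an orthonormal basis of the
identified row space under one consistent cutoff. Early-campaign fits are
rank-deficient *by design* (two-level data cannot identify quadratics), so
rank deficiency warns rather than fails. Every grid search over model
predictions is restricted to points that (a) lie in the identified row space
and (b) have prediction leverage fᵀ(XᵀX)⁺f ≤ 1.05; outside that region a
quadratic extrapolates without support, and trusting it was the single
largest source of closed-loop failures during development.

## Experiment selection and elimination

After a two-stage initialization — a randomized two-level factorial over the
full ranges (default 32 runs), then a targeted factorial in a half-shrunk box
around each candidate's best feasible observation — the loop iterates:

1. fit the shared surface to all successful droplets;
2. compute each active candidate's predicted constrained optimum on a
   resolution-rounded grid (default 21 points per dimension);
3. eliminate candidate k if UCB_k < LCB_best, with t-intervals at level α
   (default 0.05) on the fit's residual degrees of freedom, both evaluated at
   the candidates' own predicted optima. The benchmark LCB_best is taken
   over candidates whose optimum satisfies the yield floor — an infeasible
   fallback optimum is an inflated unconstrained number and must not set the
   bar. The benchmark holder, candidates with fewer than 3 runs, and the
   last survivor are never eliminated;
4. run the next droplet at the most *uncertain* predicted optimum
   (G-optimality aimed at the quantity that matters): ties break to the
   higher prediction, then a seeded draw.

Stage-1 designs use Sylvester Hadamard columns, preferring the pure
coordinate columns, with the base design order the largest power of two
dividing the run count (capped at 2^p) — so a 32-run, 3-variable design is
the full 2³ factorial replicated four times, visiting every corner.
Candidates are dealt deterministically over temperature-balanced row pairs
(every candidate sees both T levels; counts differ by at most one); the seed
randomizes run order only, so the run multiset is seed-invariant.

## Winner endgame

Once one candidate remains (or a budget deadline forces a front-runner
choice), the campaign switches from the global surface — whose job, ranking
candidates, is done — to local refinement:

* **Y_max pinning.** Two droplets at the model's predicted maximum-yield
  condition. TON-chasing alone never samples the high-yield region, and the
  relative floor is only as good as the best yield actually observed.
* **Local quadratic walking.** Central-composite designs (2^p corners,
  center, 2p axial points at a quarter of each half-range) around the
  incumbent, refit locally (trust-region radius 0.35 coded), challenge the
  local optimum, re-center on the *model* optimum (noise-averaged) and
  repeat; boundary-directed optima walk to the domain edge.
* **Verification.** The predicted optimum and its one-grid-step neighbors in
  the non-loading dimensions are replicated to ≥ 3 observations and the
  incumbent moves only on a statistically significant pooled-mean gain
  (z ≈ 1.64) or a clear floor violation. On a flat surface replicate means
  are coin flips, so an insignificant comparison keeps the model's point; a
  grossly wrong basin (every point violating the floor) restarts from the
  best observed feasible droplet.
* **Boundary snap.** If the optimum sits one step inside a bound and the
  bound predicts at least as well within one SE (and stays feasible), take
  the bound: on a saturating surface the fitted vertex wobbles one step
  inside the boundary from noise alone, while a genuinely interior optimum
  has curvature that rejects the snap.
* **Loading line search.** TON rises as loading falls until the floor bites,
  so loading is tuned by stepping down one resolution step at a time until
  two consecutive infeasible observations, replicating the straddle pair,
  and reading the crossing off a two-pass local linear regression of
  observed yield on loading (all pooled observations at the final settings).
  Leftover budget replicates the crossing neighborhood and re-reads it.

The reported optimum is therefore data-anchored in every dimension: (T, t)
by verified replication, loading by a regression crossing, with the local
model supplying the prediction and its standard error.

## In-silico droplet reactor

The simulator compresses the catalytic cycle into one effective bimolecular
step per candidate with Arrhenius temperature dependence, alongside the side
processes the optimizer must trade off: protodeboronation of the free
boronic acid (k_p), hydrolysis of a pinacol-boronate reservoir into the acid
(k_h, "controlled release"), first-order product decomposition (k_d),
first-order catalyst deactivation slowed by excess ligand
(k_dec/(1 + s_L·eq)), and L₂Pd speciation dividing the active-catalyst
fraction by (1 + K_L·eq)². Concentrations default to 0.1 M aryl halide with
a 1.1–1.3× boron stoichiometry. Observations are clip(y·(1 + σξ), 0, 1) with
σ = 2% relative, multiplicative Gaussian — a plausible droplet-HPLC
repeatability figure; real platforms show condition-dependent variance the
model does not attempt.

Integration uses LSODA (rtol 1e-8, atol 1e-10) for single droplets; dense
ground-truth tables batch all droplets sharing a time axis into one
vectorized RK45 solve, evaluated at the time grid. The independent reference
in tests is fixed-step RK4.

Presets are calibrated once to the qualitative structure of four coupling
case studies plus an excess-ligand study — structure, not wet-lab numbers:

* **I** facile aryl bromide: no side chemistry, boundary optimum at maximum
  time and temperature, bidentate-ligand candidate dominant.
* **II** sluggish aryl chloride: steep-barrier trialkylphosphine candidate
  wins at the hot/long boundary; shallow-barrier dialkylbiarylphosphines are
  relatively better cold.
* **III** unstable boronic acid: protodeboronation with a *shallow* barrier
  (cooling does not stop it, but does stop the catalyst) plus mild
  temperature-active product decomposition force a hot, short-time optimum
  (t* ≈ 2 min). The barrier ordering matters: with Ea_p > Ea_c the optimizer
  correctly escapes the side reaction by cooling down instead, and the
  short-time structure vanishes.
* **IV** thermally fragile product: steep-barrier decomposition punishes
  heat, a steep coupling barrier punishes cold — an interior optimum in both
  T and t (≈ 88 °C, ≈ 4.6 min).
* **ligand_equiv** T × excess-equivalents domain at fixed time and loading;
  without free ligand the catalyst deactivates within ~1.5 min at 110 °C,
  small excess extends its life, large excess forms inactive L₂Pd — the
  per-ligand optimum sits at ≈ 0.2–0.4 excess equivalents and the response
  at 2.0 equivalents is far below it. A pure rate-boost bonus on the
  coupling step cannot produce this interior optimum at realistic
  conversions (the yield's elasticity to the rate is below one), which is
  why stabilization acts on catalyst lifetime.

### A known, deliberate limitation: the flat constrained ridge

For any Arrhenius plant whose optimum is interior in both temperature and
time, extent-of-reaction contours make T and t nearly compensating: grid
points more than one step from the argmax still reach 97–99.9% of the
optimal constrained response on preset IV. Campaigns therefore identify the
correct candidate essentially always and land *on the ridge* — within a few
percent of the optimal response — but the exact argmax location is not
statistically identifiable at 2% noise within a 96-droplet budget, and the
location acceptance check for case IV fails honestly. Making the basin sharp
enough to locate pushes t* to the boundary, destroying the interiority the
preset exists to exercise. Cases I–III do not have this pathology.

## Kinetics module

The boron pool follows two irreversible first-order steps
(E →(k_h) B →(k_p) dead arene) with the closed forms given in the module
docstring, including the k_p = k_h degenerate limit. Fitting is joint
nonlinear least squares on the concentration scale (near-zero tails are
better behaved there than on a log scale) over any mix of acid-only and
combined-pool runs, multi-started from the early-time log-linear slope plus
log-spaced guesses; rates are optimized in log space to stay positive.
Standard errors come from the Jacobian by the delta method. With only
combined-pool data from a pure-ester start the two rates are nearly
exchangeable; the fitter probes the swapped root and flags near-ties
`ambiguous`. Initial concentrations default to the first measured point of a
pure-start run and can be given explicitly for mixed starts.

`release_plateau` quantifies controlled release as the relative variation of
the free-acid profile over a time window; rate-matched k_h ≈ k_p minimizes
it, the regime in which a slow catalyst can still couple a short-lived acid.

## Problem sizes and determinism

Closed-loop studies use 96-droplet campaigns (32-run initialization) on the
coupling presets and 48-droplet campaigns on the 2-variable ligand study;
statistical checks use 100-seed batteries (kinetic recovery, elimination
soundness on a synthetic log-quadratic plant with an exact 3σ candidate gap,
model/normal-equation agreement). All randomness flows from a single
campaign seed through independent substreams (design order, tie breaks,
per-droplet noise keyed by run index), so repeated runs are byte-identical
and inserting a droplet does not shift later noise draws.

What passing these tests shows — and does not. The simulator exercises the
optimizer against the qualitative failure modes of real campaigns
(boundary/interior optima, side-reaction time pressure, candidate ranking
reversals with temperature, ligand inhibition) under honest noise, and the
kinetics module recovers rates from realistically sparse, noisy time
courses. None of this certifies behavior on a physical platform: real
droplet chemistry has non-Gaussian, condition-dependent noise, drift,
carryover, and mechanistic structure (base, water, speciation) the
simulator deliberately omits.
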