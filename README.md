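# suzukiloop

Closed-loop, model-based optimization of Suzuki–Miyaura cross-coupling
reactions over a mixed domain: a discrete roster of precatalyst–ligand
candidates (e.g. `P1-L1` … `P1-L7`, `P2-L1`) and continuous reactor settings
— temperature (30–110 °C), residence time (1–10 min), catalyst loading
(0.5–2.5 mol%), and excess ligand equivalents (0–2). It is written for
reaction-development chemists and automation engineers running droplet-flow
(or any serial) screening platforms, and for anyone who wants to study the
algorithm itself against a realistic simulated plant.

The campaign maximizes turnover number,

    TON = yield / (loading/100),

subject to the yield staying above 90% of the maximum yield observed so far —
a calibration-free constraint. The loop is:

1. a randomized two-level factorial over the full ranges (32 droplets),
2. a targeted factorial in a shrunken box around the early leaders,
3. iterated {fit → statistical elimination → G-optimal challenge}: the
   response surface is ordinary least squares for ln(TON + ε) with
   per-candidate intercepts and temperature slopes plus shared
   linear/interaction/quadratic terms; candidates are dropped when the upper
   confidence bound of their predicted constrained optimum falls below the
   best feasible lower bound; the next droplet runs at the most *uncertain*
   predicted optimum,
4. a winner endgame: local composite designs, replication-verified optimum
   coordinates, and a loading line-search down to the yield-floor crossing.

The package also ships an in-silico droplet reactor (Arrhenius coupling per
candidate + protodeboronation, pinacol-ester "controlled release",
product decomposition, ligand-dependent catalyst deactivation, 2%
multiplicative noise) with presets for four qualitatively distinct coupling
case studies and an excess-ligand study, and a pseudo-first-order kinetics
module for boronic-acid decay / controlled-release time courses:

    E --k_h--> B --k_p--> dead arene,      t_1/2 = ln 2 / k_p.

## Worked example

Run the full closed loop against the case-III preset (an unstable boronic
acid whose protodeboronation forces short residence times):

```python
from suzukiloop import io_cli, simulator
from suzukiloop.optimizer import run_campaign

params, space = simulator.make_case_plant("III")
cfg = io_cli.CampaignConfig(
    variables=[io_cli.DEFAULT_VARIABLES[n] for n in space.names],
    candidates=[c.id for c in space.roster],
    seed=4,
)
plant = simulator.SimulatedPlant(params, space, seed=4)
state = run_campaign(plant, cfg)
o = state.predicted_optimum
print(len(state.ledger), state.active, o.candidate, o.cond_star.x)
print(round(state.best_feasible.yield_frac, 3), round(state.best_feasible.response, 1))
```

prints

```
96 ('P1-L1', 'P1-L2', 'P1-L3', 'P2-L1') P1-L1 (110.0, 1.9, 1.6)
0.665 39.1
```

Reading: the campaign spent its 96-droplet budget, eliminated the
trialkyl/triaryl-phosphine candidates, ranked the XPhos-type `P1-L1` first
among the surviving dialkylbiarylphosphines, and placed the constrained
optimum at 110 °C, 1.9 min, 1.6 mol% — short residence time because the
boronic acid decays within minutes at any temperature, hot because the
catalyst's barrier is steeper than the decay's. The best feasible droplet
actually run gave 66.5% yield and TON 39.1. The dense noiseless ground truth
for this preset is 110 °C, 1.9 min, 1.7 mol%.

The same loop drives real hardware through the CLI: `suzukiloop init` sets up
a workspace, `suzukiloop suggest` prints the next condition, `suzukiloop
record -y 0.62` appends the measured yield, `suzukiloop report` prints the
trajectory, per-candidate counts, and the best-feasible summary.
`suzukiloop run-sim` runs the loop against a simulator preset, and
`suzukiloop fit-kinetics time_courses.csv` fits (k_p, k_h) with standard
errors and half-lives.

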