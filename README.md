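# hillmc

Hill-type muscle model Monte Carlo feasibility analysis for modelling
muscular adaptations to unloading.

The package re-implements, as a tested and reusable pipeline, an analysis
of which Hill-type muscle-tendon-unit (MTU) parameters must be adjusted to
reproduce post-unloading isokinetic knee extension strength:

1. **`hillmc.hill_mtu`** — Hill-type MTU model: normalized characteristic
   curves (tendon force-strain calibrated to slope 35 at 4% strain,
   active/passive force-length, force-velocity), constant-thickness
   pennation geometry, implicit Hill equilibrium with normalized tendon
   force as a state, activation-rate limits, grouped parameter
   perturbation.
2. **`hillmc.limb_model`** — synthetic right-leg model: polynomial MTU
   lengths/velocities/moment arms over hip/knee/ankle coordinates, muscle
   grouping by knee moment arm (extensor / flexor / non-knee), strength
   scaling from muscle volumes (specific tension 60 N/cm²). The default
   configuration instantiates 40 MTUs.
3. **`hillmc.reference_gen`** — synthetic reference data: isokinetic knee
   kinematics (90°→0° flexion at 30 and 180 °/s), normative
   moment-fraction tables anchored at the 30°-flexion value, pre/post
   scenario profiles, and quasi-static *oracle* references generated from
   a known ground-truth perturbation for recovery experiments.
4. **`hillmc.collocation_ocp`** — the tracking optimal control problem:
   Legendre-Gauss-Radau direct collocation (default 50 mesh intervals,
   third-order state polynomials), volume-weighted squared-activation
   effort cost plus reserve and control penalties, moment-matching and
   Hill-equilibrium path constraints, ±25 N·m knee reserve actuator scaled
   to ±1, SLSQP solution, and the 9%-reserve feasibility rule.
5. **`hillmc.perturbation_campaign`** — Monte Carlo campaigns: uniform
   sampling of 15 grouped perturbations (3 groups × 5 parameters, bounds
   MIF 40–100%, OFL 60–100%, OPA 75–100%, MSV 50–200%, TC 40–100%),
   expansion to per-MTU parameters, batched solution, feasibility
   labelling, convergence monitoring.
6. **`hillmc.feasibility_stats`** — descriptive statistics and kernel
   densities of feasible vs infeasible draws, and forward-stepwise
   logistic regression (adjusted McFadden pseudo-R², 2.5-point inclusion
   threshold) reported as odds ratios per 1% perturbation with 99% Wald
   CIs.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; its
parameter-recovery test runs two 250-draw Monte Carlo campaigns and takes
several minutes on one CPU. Everything else finishes in ~1–2 minutes.

## CLI

```sh
hillmc build-model --out model.json                 # synthetic 40-MTU model
hillmc make-reference --out-dir refs/ --seed 0      # pre/post reference CSVs
hillmc simulate --model model.json --reference refs/reference_post_30.csv \
    --condition post --velocity 30
hillmc campaign --model model.json --reference refs/reference_post_30.csv \
    --velocity 30 --n 500 --seed 42 --out records.csv
hillmc analyze --records records.csv --out report/ --plots
```

For campaigns on the 40-MTU model at desk scale, prefer a small model
(`--extensors 3 --flexors 2 --non-knee 2`) or expect long runtimes: every
draw solves a nonlinear program.

## Notes

- The NLP is solved with `scipy.optimize` (SLSQP) using exact constraint
  Jacobians obtained by complex-step differentiation; `solve()` internally
  condenses the transcription (controls and duplicated interval-boundary
  states eliminated through the dynamics/continuity equalities) without
  changing the optimum.
- Solver failures are data, not exceptions: infeasible Monte Carlo draws
  are recorded with their status (`failed` or `capacity_prescreen`) and
  count as infeasible.
- All synthetic data (model geometry, reference magnitudes) are
  deterministic given seeds and clearly labelled stand-ins; curve
  coefficients are surfaced in `hill_mtu.CharacteristicCurves`.
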