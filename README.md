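# exorun

Planar muscle-driven simulation and experimental analysis of
**exotendon-assisted running**.

An exotendon is a passive extension spring connecting a runner's two shoes,
characterized by a stiffness `k` (N/m) and a slack length `l` (m, often
expressed as % of leg length). Worn during running it stretches as the feet
separate and can reduce the energetic cost of running. `exorun` implements
a simulation-guided design workflow for this device, plus the measurement
pipeline used to evaluate it on runners:

- **Musculoskeletal simulation.** A sagittal-plane skeleton with 20
  generalized coordinates (3-rotation + 2-translation pelvis-ground joint,
  lumbar, and hip/knee/ankle/metatarsophalangeal/shoulder/elbow joints per
  side; out-of-plane coordinates locked), 18 Hill-type muscle-tendon units
  (9 per leg), smoothed Hunt-Crossley foot-ground contact spheres (4 per
  foot), and the exotendon as a linear spring between calcaneal anchors.
- **Tracking optimization.** Direct-collocation optimal control over half a
  gait cycle with left-right symmetry, minimizing

  `J = ∫ [ Σ w_kin (q_i − q̄_i)² + Σ w_grf (ΔGRF_i)² + Σ w_act a_i² + Σ w_met Ė²_met,i ] dt`

  with `w_kin = 1e-6`, `w_grf = 14`, `w_act = 8.0`, `w_met = 4e-5`, where
  `a_i` are muscle activations and `Ė_met,i` per-muscle metabolic rates
  (smoothed Bhargava-style model).
- **Design sweep.** A 5×5 grid over stiffness {30, 60, 120, 180, 240} N/m
  and slack length {6.25, 12.5, 25, 37.5, 50}% of leg length, each solved
  at four stride durations (90–105% of natural), reporting percent change
  in average energetic cost (W/kg) versus natural running and exotendon
  tension profiles over the gait cycle.
- **Experiment analysis.** Breath-by-breath indirect calorimetry to net
  metabolic power (Brockway equation, final-minute averaging, standing
  baseline subtraction, RER > 1.0 exclusion), exotendon tension from shoe
  marker distances (`tension = k · max(0, ‖p_L − p_R‖ − l)`), gait-cycle
  segmentation, and paired t-tests with Bonferroni correction (4 in-lab
  comparisons; 3 track metrics).
- **Synthetic data.** Generators for periodic reference running gait with
  weight-balancing ground reaction forces, marker trials with known
  ground-truth tension, and calorimetry datasets with injected condition
  effects — so the entire pipeline is testable with known answers.

It is aimed at researchers in biomechanics / assistive-device design who
want a self-contained, scriptable version of this workflow.

## Worked example

```python
import exorun
from exorun import skeleton as sk, synth, tracking as tr, sweep as sw
from exorun.contact import ExotendonSpec

model = sk.scale_model(sk.build_default_model(), sk.ScaleSpec(1.78, 73.0))
ref = synth.generate_reference_gait(speed=4.0, stride_duration=0.70,
                                    seed=0, model=model)
cfg = tr.OcpConfig(mesh_intervals=8, maxiter=400)

natural = tr.solve_tracking(model, ref, None, cfg)
exo = ExotendonSpec.from_percent(120.0, 25.0, name="medium-original")
assisted = tr.solve_tracking(model, ref, exo, cfg)

print(f"natural:  {natural.average_cost_w_kg:.2f} W/kg")
print(f"assisted: {assisted.average_cost_w_kg:.2f} W/kg")
print(f"change:   {sw.percent_change(assisted.average_cost_w_kg, natural.average_cost_w_kg):+.1f}%")
```

On the default coarse mesh this prints (a few minutes per solve on one CPU):

```
natural:  18.93 W/kg
assisted: 11.54 W/kg
change:   -39.1%
```

i.e. the spring-assisted simulation predicts a lower average whole-body
muscle metabolic rate than natural running at the same 4 m/s speed; the
magnitude at this coarse mesh greatly overstates what finer transcriptions
predict (see `docs/methods.md` on mesh resolution and local minima). The same workflow is available from the shell:

```sh
exorun simulate --speed 4.0 --exotendon medium-original --mesh 8 --out out/
exorun sweep --grid "120,240:25,37.5" --stride-scales 1.0 --out sweep/
exorun synth calorimetry --seed 1 --out data/
exorun stats --table results.csv --family inlab --out stats/
```

## Layout

| module | contents |
| --- | --- |
| `exorun.skeleton` | planar 20-coordinate skeleton, scaling, kinematics, Newton-Euler dynamics |
| `exorun.muscles` | Hill-type curves, activation dynamics, fiber-tendon equilibrium, metabolic model |
| `exorun.contact` | smoothed Hunt-Crossley spheres, exotendon spring, named design presets |
| `exorun.tracking` | reference data, objective, collocation transcription, solver |
| `exorun.sweep` | design grid, stride-duration selection, percent changes, tension profiles |
| `exorun.analysis` | calorimetry, marker tension, gait segmentation, paired statistics |
| `exorun.synth` | synthetic gait / marker / calorimetry / track generators with ground truth |
| `exorun.mocapio` | TRC and STO/MOT readers and writers |
| `exorun.cli` | `exorun` command-line interface |
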