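# alleesense

Simulation and analysis toolkit for an **Allee-effect-based distributed
detection algorithm** for microbial whole-cell sensors (MWCS) — engineered
microbial populations that sense an analyte and report it collectively.

## The problem and the model

A lone engineered cell that reports an analyte on local detection gives a
population readout that is merely proportional to the fraction of detecting
cells, and any realistic circuit also fires spuriously. The algorithm
studied here couples the cells through quorum sensing so that the
*population* thresholds, amplifies, and remembers a detection, while
absorbing spurious single-cell events.

Cells occupy one of two logical states — L ("analyte absent") or H
("analyte present") — with densities `L(t)`, `H(t)` and a conserved total
`P = H + L` (mL⁻¹). Three reactions move cells between them:

* **Set** (`L → H`, rate `σ·L`): true detections plus errors, with the
  rare-event detection rate `σ = σ_A·A + σ_err` for analyte concentration
  `A`;
* **Hold** (`L + H → 2H`, rate `κ · Hⁿ/(Hⁿ+Kⁿ) · L`): quorum-sensing
  positive feedback with a cooperative Hill activation (n > 1);
* **Reset** (`H → L`, rate `ρ·H`): relaxation that absorbs spurious flips.

Eliminating `L = P − H` gives a single bistable ODE,

```
dH/dt = σ·(P−H) + κ · Hⁿ/(Hⁿ+Kⁿ) · (P−H) − ρ·H
```

whose cooperative feedback produces an Allee effect for the H "species":
below a tipping density the reset reaction wins and the population relaxes
to a low state; above it the feedback takes over and the population commits
to a high, self-maintaining state — a latched, easily read detection
signal. The central quantity is the **critical rate σ_c**, the saddle-node
value of σ at which the low and middle equilibria merge: below it spurious
detections are absorbed, above it the population is guaranteed to commit.

The package provides:

* the ODE right-hand sides of this model and of three comparison
  algorithms (memoryless set-reset, naive broadcasting, and quorum-sensing
  distributed amplification with a secreted reporter);
* exact equilibrium finding with stability labels, the bistability
  feasibility condition, and the tipping/committed population fractions
  `α_i`, `α_f`;
* σ_c by bisection on the equilibrium count, plus (κ, ρ) heat-map sweeps;
* transient simulation under constant or piecewise analyte profiles, with
  steady states, 95% convergence times, memory (hysteresis) experiments,
  and dose–response comparison curves;
* hybrid stochastic–deterministic robustness runs, where a Gillespie
  birth–death process of spurious events drives σ(t).

## Worked example

```python
import alleesense as al

p = al.AlgorithmParameters()          # κ=35 h⁻¹, ρ=14 h⁻¹, n=4, K=8e7 mL⁻¹, P=1.5e8 mL⁻¹
print(al.find_sigma_c(p).sigma_c)     # 3.05523681640625
print(al.alpha_bounds(p))             # (0.4366860325231863, 0.6148157713857774)
print(al.table2_summary(p))
```

```
   sigma  steady_state  convergence_time    terminal_H
0   0.00  0.000000e+00          0.000000  0.000000e+00
1   1.50  1.488097e+07          0.206578  1.488097e+07
2   3.04  3.584287e+07          0.600090  3.584241e+07
3   4.00  1.014268e+08          0.433784  1.014268e+08
4   5.00  1.029713e+08          0.290879  1.029713e+08
```

The critical rate is σ_c ≈ 3.055 h⁻¹ — about 22% of the slowest rate
constant ρ — and the tipping/committed fractions are α_i ≈ 0.44 and
α_f ≈ 0.61 of the population. The table shows, for each constant σ, the
steady-state H density reached from a cold start (H(0) = 0) and the time to
reach 95% of it: below σ_c (0, 1.5, and the near-critical 3.04 h⁻¹) the
population settles on the low "no detection" branch, above it (4, 5 h⁻¹) it
commits to the high branch, and convergence is slowest closest to σ_c
(0.60 h at σ = 3.04 versus 0.29 h at σ = 5).

The same analyses are available from the shell:

```bash
alleesense sigma-c
alleesense table2 --out table2.csv
alleesense simulate --sigma 4 --t-end 2 --out traj.csv
alleesense compare --a-max 6 --out dose_response.csv
alleesense robustness --n-runs 20 --seed 0 --out robustness.json
alleesense sweep --grid-size 64 --out sigma_c_grid.csv
```

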