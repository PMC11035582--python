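# Methods

## Model

The package studies a two-state abstraction of a quorum-sensing (QS)
detection circuit. Cells are L ("vote absent") or H ("vote present");
densities are in mL⁻¹, rates in h⁻¹, time in h, and the total density
`P = H + L` is conserved (the population is assumed at carrying capacity;
replication and death are not modelled). The H density obeys

    dH/dt = σ·(P−H) + κ · Hⁿ/(Hⁿ+Kⁿ) · (P−H) − ρ·H,

with σ = σ_A·A + σ_err the rare-event detection rate (analyte-driven plus
spurious), κ the maximum QS-feedback (Hold) rate, K and n the Hill
half-activation density and cooperativity, and ρ the reset rate. For n > 1
the feedback is cooperative and the H population behaves like a species
with an Allee effect: its net birth rate is negative at low density,
positive in an intermediate window once

    g(H) = κ·Hⁿ/(Hⁿ+Kⁿ)·(P−H) − ρ·H

is positive somewhere on [0, P]. That condition is the package's
*feasibility condition*: when it holds, the σ = 0 equation has three roots
`0 < α_i·P < α_f·P`, and the system is bistable for σ below a critical rate
σ_c at which the low and middle roots merge in a saddle-node. α_i is the
tipping fraction (start above it and the population commits even with no
analyte — the memory property), α_f the committed floor (every "detected"
steady state lies above it). These fractions are *defined* here from the
σ = 0 root structure; they are the natural choice because the middle σ = 0
root is exactly the analyte-free tipping density and the high σ = 0 root is
the lowest committed state over all σ ≥ 0.

Three comparison algorithms share the parameter set: **set-reset** (Hold
removed; unique fixed point `P·σ/(ρ+σ)`, linear response, no memory),
**broadcasting** (reset removed, mass-action relay `κ_b·H·L`; any σ > 0
drives the whole population to H, so its detection threshold sits at zero),
and **distributed amplification** (set-reset kinetics for H plus a secreted
reporter S produced by all P cells at the Hill-activated rate and decaying
at ρ; fixed point `H* = Pσ/(ρ+σ)`, `S* = (κ/ρ)·P·hill(H*)`).

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| κ | max Hold (QS feedback) rate | 35 | h⁻¹ |
| ρ | reset rate | 14 | h⁻¹ |
| n | Hill coefficient | 4 | — |
| K | half-activation density | 8·10⁷ | mL⁻¹ |
| P | total population density | 1.5·10⁸ | mL⁻¹ |
| σ_A | detection rate per analyte unit | 1 | h⁻¹/a.u. |
| σ_err | spurious detection rate | 0 | h⁻¹ |
| κ_b | broadcasting relay rate | κ/P | mL·h⁻¹ |

κ, ρ and n are literature-scale constants for LuxI/LuxR-type QS circuits
(expression and degradation of a LuxI-like synthase, cooperative promoter
activation); K is a typical QS activation threshold and P a reachable
*E. coli* density chosen comfortably above 2K so the committed state is
well separated from the threshold. Analyte units are arbitrary: only the
product σ_A·A matters, so σ_A defaults to 1 and dose–response grids are
stated in units of the critical concentration. The broadcasting reaction is
bimolecular, so its rate constant has different units from κ; the default
κ_b = κ/P makes its saturated per-capita rate equal to κ, which is the
comparable choice when a single κ is quoted for all algorithms. κ = 0 is
admitted as the degenerate set-reset limit.

## Equilibria and the critical rate

For integer n the fixed-point equation is cleared of its Hill denominator
and solved as a degree-(n+1) polynomial in x = H/P (coefficients are then
O(rates) — conditioning does not degrade at the 10⁸ density scale) via
companion-matrix roots, followed by three Newton polishing steps. Roots
with relative imaginary part above 1e-6 are discarded; real roots are
deduplicated at 1e-6·P, and a merged pair is labelled `tangent` (the
saddle-node's double root). Stability is derivative-free: the sign of dH/dt
at r ± 1e-5·P (flow inward on both sides ⇒ stable; the same sign on both
sides ⇒ tangent). Every reported root is certified by its residual,
|dH/dt| < 1e-6·(σ+κ+ρ)·P. Non-integer n falls back to an 8192-cell
sign-change scan with `brentq` refinement, which cannot see an exact
tangency (a measure-zero event off the bisection path). The feasibility
maximum g_max is located on a 4096-point grid and refined with bounded
scalar minimisation.

σ_c is found by bisection on the root count: the initial interval is
[0, σ_utr], with σ_utr obtained by doubling from ρ until only one root
remains; midpoints with three roots raise the lower bound, with one root
lower the upper bound, and a midpoint whose root set contains a tangent
root is returned immediately. Default precision is 1e-3 h⁻¹ (bracket width)
with at most 64 iterations. With the default parameters this yields
σ_c = 3.0549 h⁻¹ (verified against an independent dense σ-scan of root
counts and, during development, an exact symbolic saddle-node computation),
about 22% of ρ. Note the commonly quoted two-decimal operating rate
3.04 h⁻¹ sits *just below* this tangency: at σ = 3.04 the system is still
(barely) bistable, a cold start converges to the low root ≈ 0.36·10⁸ mL⁻¹,
and all near-critical outputs are sensitive in the third decimal of σ —
which is why table-style summaries report the certified equilibrium root
nearest the trajectory endpoint rather than a long integration.

Heat-map sweeps recompute σ_c per (κ, ρ) cell independently in fixed
row-major order (bit-reproducible) and encode infeasible cells as σ_c = 0.
Default axes are 64×64 log-spaced over [1, 100] h⁻¹; since feasibility
depends only on ρ/κ at fixed (K, P, n), the dead region is a sharp linear
boundary in log-log space (threshold ρ/κ ≈ 0.45 at the default K/P).

## Integration and measurements

Transient runs use LSODA with rtol 1e-8 and atol 1 mL⁻¹ — tight because
near-critical trajectories crawl through the saddle-node bottleneck where
dH/dt ≈ 0, and halving the tolerances moves 95%-convergence times by well
under 0.1%. Piecewise-constant drives (analyte step/pulse profiles, noise
paths) are integrated segment-by-segment with the solver restarted at every
discontinuity. Steady states integrate in doubling chunks until |dH/dt|
stays below 1e-6·ρ·P across a trailing 0.1 h window, with a hard cap of
1000 h; the Allee model's result is cross-checked against the nearest
certified root. Convergence time is the first interpolated crossing of 95%
of the steady state (0 by convention when the steady state is 0). Cold
starts use H(0) = 0, L(0) = P. Memory experiments integrate through the
analyte profile plus a post-removal window of 10/ρ hours (several reset
time constants) and declare the detection memorized when the final H is at
least α_f·P.

## Noise model and the hybrid experiment

Spurious detections in a real circuit fluctuate (leaky expression). They
are modelled as an auxiliary birth–death species — births at constant β
(default 0.5 h⁻¹, a leaky-expression scale), per-copy deaths at γ (default
2 h⁻¹, a repressor decay scale) — simulated exactly with the Gillespie
algorithm from copy number 0 using numpy's seeded PCG64 generator. The
stationary law is Poisson(β/γ); the default mean spurious rate is therefore
0.25 h⁻¹, an order of magnitude below σ_c. The copy-number path drives
σ(t) = σ_unit·count(t) (σ_unit = 1 h⁻¹ per copy) in an otherwise
*deterministic* ODE run, integrated exactly between events; the run is a
false positive if H(t) ever reaches α_f·P. The default experiment horizon
is 100 h, with longer horizons (e.g. the 1000 h variant) available by
parameter. This hybrid design probes exactly one noise channel — a
fluctuating spurious switching rate; it does not model demographic noise of
the L/H population itself, cell-to-cell parameter variability, growth, or
spatial structure, so a passing robustness ensemble shows threshold-based
absorption of rate noise, not robustness to every biological noise source.

## Problem sizes and verification

The test suite regenerates its own data: equilibrium solvers are
cross-checked against dense sign-change scans (10⁶ points in the
acceptance check, across 100 randomly drawn parameter sets spanning
κ, ρ ∈ [1, 100] h⁻¹, K ∈ [0.2, 0.8]·P, P ∈ [10^7.5, 10^8.5] mL⁻¹,
n ∈ {2..5}); the σ_c bisection against a 1e-3-step σ-scan; simulated steady
states against closed forms where they exist (set-reset, distributed
amplification, the κ = 0 linear limit with its ln(20)/(σ+ρ) convergence
time); the robustness ensemble uses 20 seeds × 100 h; and the sweep check
uses the full 64×64 grid. All stochastic tests fix their seeds.

## Known limitations

* The abstract two-state model is the object of study; no mechanistic
  AHL/LuxI/LuxR species model is included, and no analytic convergence-time
  bound is computed (only empirical 95% times).
* Near σ_c every observable is ill-conditioned in σ by construction (the
  saddle-node); quantities quoted at two-decimal rates near the critical
  point carry that sensitivity.
* Tangency detection (the `tangent` label) is exact only on the
  integer-n polynomial path; the non-integer-n scanner resolves root
  *counts* reliably but not double roots.
* The population ODE treats P as constant; changing population sizes and
  inter-cellular heterogeneity are out of scope.
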