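# Methods

## Model

The community metabolic map is deliberately minimal.  Balanced
metabolites: glucose, the private intermediates I1, I2 (and I3 for the
three-cell system), and the common goods X and Y.  Boundary species:
CO₂, a by-product, and one biomass species per cell type.  Reactions
(C-mol/step; identifiers fixed): `GLCIN` (0 ≤ flux ≤ influx), `GTI1/2/3`
(glucose + X + Y → I*i*), `DI1X`, `DI3X` (I → 4X + CO₂), `DI2Y`
(I2 → 4Y + CO₂), `BM1/2/3` (I*i* → biomass, with `BM1` consuming *b*
C-mol of I1 per C-mol biomass), and `OMEGA` (glucose → by-product).
Biomass species are sinks of the LP; cell-number bookkeeping lives in
the engine.  The glucose influx is modeled as an upper bound rather
than a fixed flux so that capacity-limited states remain feasible; at
the unconstrained optimum the bound is tight.

FBA maximizes total biomass synthesis.  With unit influx the optimum is
0.5 C-mol/step for both networks.  The optimum is degenerate; reported
flux vectors are made backend-independent by lexicographically
minimizing the by-product flux, then total CO₂, at the fixed optimum,
and flux variability analysis (per-flux min/max at the fixed optimum)
characterizes the full optimal set.

**Growth bias for b ≠ 1.**  The bias β is defined on biomass synthesis
in C-mol terms, β = (BM2 − b·BM1)/2, which equals the glucose-
consumption bias (v₂,g − v₁,g)/2.  For b = 1 this is simply half the
difference of the biomass fluxes.  This is the definition under which
the cost asymmetry pins the optimum: β ≡ +0.25 for b = 2 and −0.25 for
b = 0.5, while b = 1 leaves β free in [−0.25, +0.25].  (On the raw
biomass-flux difference, b = 0.5 would give −0.5.)

## Stepwise-growth dynamics

Per-step biomass bounds allocate the 0.5 C-mol/step growth allowance in
proportion to μᵢBᵢ times regulation factors (powers of the other types'
cell numbers); all variants share a common denominator so the bounds
always sum to (1 − ω)/2 exactly.  Conventions: 0⁰ := 1, so a zero
elasticity degenerates to the unregulated ratio; the regulation factor
is the cell number itself (identity form) by default, with the
receptor-occupancy form B/(B + K_d/α) available (`factor_form=
"hyperbolic"`, K_d/α ∈ {0.2, 1, 5} giving qualitatively identical
behavior); biomasses are expressed in billions so identity factors stay
in (0, 1] in the regimes of interest (values > 1 are allowed and the
power is applied unchanged).

The update is explicit Euler with first-order death:
Bᵢ(t+ts) = Bᵢ(t)(1 − d) + ts·bᵢ,FBA, with biomass clamped to 0 below
10⁻¹² billions.  Defaults: ts = 0.1 month, d = 0.05 per step (0.5 per
month).  The per-step death fraction is the parameter because the two
equivalent "rate constant" spellings (0.05/ts and 0.5 per month) meet
there, and because it reproduces the analytic balanced states: total
biomass ts·0.5/d = 1.0 billion, composition B = (μ₁, μ₂)/(μ₁+μ₂) at
ε = 1.  μ values enter only as ratio weights, so their absolute unit is
immaterial.

**Flux timing.**  The equations index bounds at t+ts as functions of
B(t), while the biomass update at t+ts consumes fluxes indexed t.  The
engine follows this literally: the flux applied over a step derives
from the state one step earlier (the first step uses the initial
state).  This one-step pipeline shifts transient timings by a few
steps — e.g. the untreated tumor's critical crossing lands at 9.5
months rather than 8.8 under the no-lag variant — and is the convention
all reported times use.  After a therapy intervention the pipeline
restarts from the post-intervention state (the 80%-kill re-crossing at
12.1 months depends on this).

**Capacity and degenerate allocation.**  With capacity enabled, each
common-good conversion flux is capped at V_max·Bᵢ (V_max = 3 per unit
biomass; the X caps of types 1 and 3 add).  The per-step LP then has
optimum min(Σb_ub, T/2) with throughput T = min(influx, 4V_maxB_X,
4V_maxB_Y) — but the split of a capacity-limited optimum between cell
types is degenerate.  The engine resolves it by scaling all bounds by a
common factor, which is exactly the ω-replacement rule
1 − ω = min(1, 4V_maxB₁, 4V_maxB₂): `omega_mode="eq10"` (scale the
bounds) and the default LP-cap path are verified identical in the
tests.  `lp_mode="always"` solves the LP with scipy/HiGHS at every step
and reproduces the closed-form trajectories to 10⁻⁹; the default
`"auto"` uses the closed form directly (two-cell capacity binds exactly
when a producer drops below 1/12 billion).

This proportional choice matters for one scan only (below): any rule
that instead starves specific cell types when capacity binds changes
which marginal trajectories recover.

## Classification and scans

A run is classified over a 20-month tail window (per-step relative
change ≤ 10⁻⁶ for the persisting types): *coexistence* (all types above
0.01 billion, steady), *exclusion* (a steady subset persists),
*collapse* (everything extinct), else *unstable*.  Independently, the
*instability time* records the first step at which a normal (social)
type drops below 0.1 billion.  Horizons are 200 months (2000 steps),
long enough for every scan trajectory to settle.

Scans: ε on a 0.01 grid with μ = (0.25 − β, 0.25 + β) and the
bias-matched initial composition B(0) = 2μ (thresholds 0.17 / 0.36 /
0.92 at β = 0.05 / 0.1 / 0.2); γ from the initial composition
(0.39, 0.59, 0.02) with ε = 1 — mutual mode on a 0.05 grid (smallest
stable value), one-way mode on a 0.1 grid (smallest value at which the
normal pair excludes the transformed type: 0.4).  Scans stop at the
first achieved grid point by default; `full=True` continues and reports
whether the achieved region is contiguous.

## Therapy

Interventions trigger on the tumor's cell number reaching 0.4 billion
(evaluated once per step, after the update, initial state included) or
at fixed times; several interventions in one step execute in plan
order, and a `skip_first` counter lets an intervention act only from a
later crossing (the dual-kill + death-boost plan applies the tripled
death rate at the second crossing only).  The resistant clone (type 4)
copies the tumor's growth parameters with responsiveness ε1 = 0; its
seed biomass is not pinned by the model and defaults to 0.01 billion —
tests verify the qualitative outcome (clone expands while the treated
tumor declines) for seeds 0.005–0.02.

## Known limitations and deviations

- **Mutual-γ threshold.**  Under the printed mutual-regulation
  equations with proportional capped allocation, the smallest stable γ
  from (0.39, 0.59, 0.02) is 0.5 — robust here to step size (0.01–0.5
  month), flux-timing convention, death rate, extinction clamp, and the
  hyperbolic factor.  A γ = 0.2 run is unstable and γ = 0.5 is stable,
  bracketing the transition; values nearer 0.3 arise only under
  degenerate-vertex LP allocations that starve type 3 when capacity
  binds, which this package deliberately does not adopt.  Small γ is
  *destabilizing* in this formulation: with B₃ ≪ 1, the factor B₃^γ
  suppresses the normal types' bounds more than the mutant's.
- **Single-kill instability extension.**  With the flux-timing and
  intervention conventions above (which pin the 9.5- and 12.1-month
  crossings exactly), the single 80% kill extends the instability time
  by ~16% (12.4 → 14.4 months), somewhat above the ~10% ballpark quoted
  for this effect.
- A "slower" asocial mutant only grows at all for μ₃ ≳ 0.12 against the
  (0.2, 0.3) pair at its balanced state (its specific growth
  0.5μ₃/denominator must exceed the 0.5/month death rate); the
  lower-μ₃ showcase therefore uses μ₃ = 0.15.
- The by-product is a pure carbon sink (glucose → by-product at flux
  ω); its stoichiometric fate is not otherwise specified.
- Asymmetric X/Y stoichiometries, genome-scale maps, stochastic death,
  and spatial structure are out of scope; `xy_stoich` applies one
  integer to both common goods.
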