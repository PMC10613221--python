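# dcfba — dynamic competition flux balance analysis

`dcfba` simulates communities of cell types that compete for a shared
carbon substrate while depending on each other's products and growth
signals.  It is aimed at systems/computational biologists who want a
constraint-based (FBA-style) alternative to fully kinetic models for
questions about cell–cell competition: when does one cell type
competitively exclude another, what strength of cross-regulation
("socialness") is needed for stable coexistence, why can an *asocial*
mutant — a tumor-like cell that stops responding to growth regulation —
outgrow faster-dividing neighbors, and how do cytotoxic or
regulation-restoring therapies change that outcome.

## The model

Two (or three) cell types grow on glucose through a toy stoichiometric
network: type *i* converts glucose to a private intermediate I*i*
(consuming one unit of each "common good" X and Y per conversion) and
spends the intermediate either on its own biomass or on common-good
synthesis (I1 → 4X + CO₂ by type 1, I2 → 4Y + CO₂ by type 2).  At each
time step *ts* a linear program maximizes total biomass synthesis
subject to steady-state mass balance; at unit glucose influx the
optimum is 0.5 C-mol/step (half the carbon becomes biomass, half CO₂).

Because that optimum is degenerate, the split between cell types is set
by biomass-dependent upper bounds on the biomass-synthesis fluxes.  In
the regulated two-cell system,

    b₁,ub = 0.5·μ₁B₁B₂^ε / (μ₁B₁B₂^ε + μ₂B₁^εB₂),   b₂,ub symmetric,

where μᵢ are inherent specific growth rates, Bᵢ cell numbers (billions,
1-L vessel) and ε the elasticity with which each type's growth responds
to the other's abundance (a growth-factor/receptor signal).  Cell
numbers then follow stepwise Euler dynamics with first-order death,

    Bᵢ(t+ts) = Bᵢ(t)·(1 − ts·k_D) + ts·bᵢ,FBA(t),

with capacity limits capping each common-good flux at `3 ×` the
producer's cell number.  Three-cell variants add an X-producing mutant
(elasticities ε1, ∂ toward the social pair) and mutual or one-way
cross-regulation of strength γ.  The analysis layer classifies
trajectories (coexistence / exclusion / collapse / unstable), scans ε
and γ for stability thresholds, and runs trigger-based therapy plans
(instantaneous kills, death-rate boosts, regulation restoration,
drug-resistant clones).

## Worked example

```python
from dcfba import *

net = build_two_cell_network(b=1.0)          # 8 reactions, 5 balanced metabolites
fr = flux_variability(net)
print(solve_fba(net).objective_value)        # 0.5
print(beta_range(fr))                        # (-0.25, 0.25)

cfg = SimConfig(horizon=200.0, mu=[0.2, 0.3], initial_B=[0.4, 0.6],
                regulation=RegulationSpec(mode="two_cell_regulated", epsilon=1.0))
traj = simulate(cfg)
print(classify(traj).label, traj.final_B())  # coexistence [0.4 0.6]

print(scan_min_epsilon(0.05).threshold)      # 0.17
```

The FVA lines say that the optimal community wastes nothing on
by-product and can split growth arbitrarily between the two types
(growth bias β between −0.25 and +0.25) when both biomasses cost the
same.  The simulation shows that full regulation (ε = 1) holds the
composition at the analytic balanced point B = (μ₁, μ₂)/(μ₁+μ₂)
billions indefinitely, and the scan finds the smallest elasticity that
still achieves coexistence at growth bias 0.05: ε = 0.17.  Without
regulation the same community collapses — `dcfba scenario fig2_collapse
--out out/` reports the capacity limit first binding at t = 11.7 months,
after which both cell types decline to zero.

The same functionality is available from the shell:

```bash
dcfba fva --b 1
dcfba scan epsilon --beta 0.05 --out out/
dcfba scenario fig8_therapy --plan single --out out/
```

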