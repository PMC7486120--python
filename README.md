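# ecosim

A simulator and analysis library for **serial-dilution consumer-resource
ecosystems with metabolic trade-offs** — microbial communities that receive
nutrients as periodic boluses, grow until depletion, and are diluted back to
a fixed inoculum density, batch after batch.

It is aimed at theoretical ecologists and microbiologists studying how
intermittent ("seasonal") nutrient supply shapes community diversity:
when does a bolus-fed community mimic a chemostat, when does competitive
exclusion take over, and how do cross-feeding, unequal enzyme affinities or
yields, finite-population bottlenecks, and migration modify the
nutrient-diversity relationship.

## Model

A species σ is an enzyme-allocation strategy α⃗σ over p substitutable
nutrients, constrained by a total enzyme budget: Σᵢ ασ,ᵢ = E + ε ξσ with
ξσ ~ N(0,1) (ε = 0 gives exact trade-offs and places every strategy on the
nutrient simplex). Within a batch, uptake follows Monod kinetics,

    jσ,i = ασ,i · ci / (Ki + ci),
    dci/dt = − Σσ ρσ (jσ,i − Σᵢ′ Γi,i′ jσ,i′),
    dρσ/dt = ρσ Σᵢ Yi jσ,i,

where Γ is an optional byproduct (cross-feeding) matrix and Yᵢ are biomass
yields. Each batch starts from total inoculum density ρ0 and bolus
concentration c0, and runs to nutrient depletion; dilution renormalizes the
final biomass back to ρ0. The fold increase of a species over a batch is
exp(α⃗σ · Y⃗I⃗) with the Monod integrals Iᵢ = ∫ cᵢ/(Kᵢ+cᵢ) dt, which the
integrator carries as auxiliary quadrature states — equal yield-weighted
Monod integrals are the condition for neutral coexistence of all strategies.

The analysis layer provides the chemostat-limit steady-state balance
(c0 ≪ K), invasion fitness of rare strategies, *remapped* coexistence
boundaries (the supply at which all nutrients are equally valuable for a
given resident, which shifts with bolus size and drives the "early-bird"
loss of diversity at c0 ≈ K), the convex-hull coexistence criterion,
effective-species diversity m_e = exp(−Σ P ln P), stochastic bottlenecks
with spike-in migration, and diversity-versus-bolus-size sweeps.

## Worked example

```python
import numpy as np
from ecosim import (Environment, make_equally_spaced_strategies,
                    run_to_steady_state)

strategies = make_equally_spaced_strategies(21)          # 21 strategies on [0,1]
env = Environment(c0=1.0, supply_fraction=[0.05, 0.95], K=1.0, rho0=1e-3)
res = run_to_steady_state(np.full(21, 1/21), strategies, env)
print(f"batches={res.batches_used} converged={res.converged} "
      f"survivors={res.n_survivors} m_e={res.diversity().m_e:.4f}")
```

prints

```
batches=61 converged=True survivors=13 m_e=1.7012
```

With a strongly skewed bolus at c0 = K, the community converges in 61
batches and diversity collapses from the maximal 21 effective species to
about 1.7: the species favouring the abundant nutrient gain an early-bird
advantage and absorb most of the biomass, and eight species favouring the
scarce nutrient are driven below the extinction floor. Re-running with
`supply_fraction=[0.5, 0.5]` keeps the community perfectly even
(`m_e=21.0000`), and with `c0=1e-4` or `c0=1e4` the same skewed bolus
yields m_e ≈ 3.9 — the U-shaped nutrient-diversity relation.

The same protocols are available from the shell:

```sh
ecosim sweep --preset baseline --out sweep.csv
ecosim remap --strategy 0.2,0.8 --c0 1.0
ecosim hull --points "0,1;0.5,0.5;1,0" --supply 0.3,0.7
```

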