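# Methods

## Model and assumptions

The simulator implements a consumer-resource model of batch growth under
serial dilution. A community is a set of species, each defined by a fixed
enzyme-allocation strategy α⃗σ over p substitutable nutrients (all nutrients
belong to one limiting class; complementary nutrients are out of scope).
Uptake of nutrient i by species σ is Monod-limited,
jσ,i = ασ,i cᵢ/(Kᵢ+cᵢ), all nutrients are consumed simultaneously, and
growth converts nutrient to biomass with per-nutrient yield Yᵢ (Yᵢ = 1
means one unit of nutrient concentration becomes one unit of biomass
density). There are no lag phases, maintenance costs, death rates, or
nutrient inflow during a batch.

Metabolic trade-offs are imposed through the budget constraint
Σᵢ ασ,ᵢ = E + ε ξσ with standard-normal ξσ and E = 1 by convention. Exact
trade-offs (ε = 0) are the equalizing mechanism that permits diversity
beyond competitive exclusion; ε > 0 creates a fitness hierarchy. Because a
Gaussian draw can produce a non-positive budget when ε is large, draws are
rejected and redrawn (with the rejection count reported); at the canonical
ε = 0.1 a rejection requires a 10σ event and effectively never occurs.

Cross-feeding is a byproduct matrix Γ: consuming one unit of nutrient i′
releases Γ_{i,i′} units of nutrient i at no enzymatic cost, i.e. production
is tied to consumption. The canonical bitrophic setup supplies only
nutrient 2 with Γ = [[0, γ], [0, 0]]; integrated production of nutrient 1
then equals γ·c₂(0) exactly, so the total consumable nutrient is
(1+γ)·c₂(0). How byproduct stoichiometry should interact with unequal
yields is deliberately left undefined; the cross-feeding analyses here use
unit yields.

## Batch integration

One batch integrates ρ⃗, c⃗, the Monod integrals Iᵢ = ∫ cᵢ/(Kᵢ+cᵢ) dt and
the cumulative byproduct production as one coupled ODE system (the
integrals are quadrature states of the same solve, never post-hoc
quadrature on sampled output). The solver is SciPy's LSODA with relative
tolerance 1e-10 and absolute tolerance 1e-14; concentrations are clamped at
zero inside the right-hand side to suppress harmless negative undershoot.

Exact depletion takes infinite time (the final decay of c is exponential),
so a batch ends when the remaining consumable nutrient falls below a
fraction 1e-9 (configurable) of everything supplied, bolus plus byproducts,
located by event root-finding rather than step truncation. Tests verify
that tightening this threshold to 1e-12 moves the Monod integrals by less
than 1e-6 relative. An alternative fixed-duration mode stops at a set batch
length for incomplete-depletion protocols.

Two independent identities serve as integration oracles: (i) with unit
yields and no byproducts, Σρ + Σc is conserved along the trajectory and the
final biomass is ρ0 + c0; (ii) for every species,
ρσ(t_f)/ρσ(0) = exp(Σᵢ ασ,ᵢ Yᵢ Iᵢ), which follows from the growth law
independent of the integrator's path. The fold identity holds to 1e-6
relative across randomized communities, including unequal K, Y and
cross-feeding.

With unequal yields the growth rate is ρσ Σᵢ Yᵢ jσ,i while consumption
remains in concentration units; unit yields recover the symmetric model
exactly. Supply compositions stated "in yield units" are converted to
concentration fractions as fᵢ/Yᵢ renormalized.

## Serial dilution and steady state

Dilution renormalizes the final biomass to the inoculum density ρ0;
the protocol iterates until the inoculum composition stops changing.
Convergence is declared when the maximum per-species relative change per
batch stays below a tolerance (default 1e-8) for 3 consecutive batches.
Species whose relative abundance has dropped below 1e-10 are excluded from
the criterion: a species in geometric decline never stops changing in
relative terms, and near coexistence/exclusion transitions the approach to
steady state slows down critically, so runs are capped at a configurable
maximum number of batches and report the measured per-batch contraction
factor instead of running forever. The tolerance cannot usefully be set
below ~1e-9: per-batch composition changes are only resolved to the
integrator's accuracy, and some configurations exhibit an ultra-slow
quasi-neutral drift at that floor (about 1.5e-9 per batch for a 21-species
community at c0 = K under strongly skewed supply), so the default stays an
order of magnitude above it.

Survivors are species that are not in sustained geometric decline: relative
abundance above 1e-10 and a per-batch fold of relative abundance of at
least 1 − 1e-6 over the last ten batches. The classification is applied to
the state actually reached; on non-converged runs residual transients can
mimic slow decline, so survivor counts should be read together with the
convergence flag.

Seasonal single-nutrient supply is modeled by a periodic bolus schedule
(one pure nutrient per batch, spread over a cycle so the long-run
proportions match the target composition); steady state is then assessed
cycle over cycle.

## Stochastic bottlenecks and migration

The finite-population protocol converts final biomass to integer cells with
mass quantum ρ0/n_cells (fractional cells resolved by stochastic rounding),
draws n_cells − n_spikein resident cells without replacement (multivariate
hypergeometric) and adds n_spikein migrant cells drawn multinomially from a
fixed global pool. The canonical configuration is 1008 cells per inoculum,
of which 50 are spike-ins from a uniform 21-species pool (50 cells over 21
species cannot be exactly even, hence the multinomial). The exact
integerization scheme is a package choice; sampling is unbiased (verified
against the final biomass fractions over 10⁴ replicates) and bit-reproducible
from a seed. Reported abundances are arithmetic means of post-burn-in
inoculum fractions, with burn-in defaulting to half the run.

## Analysis layer

**Chemostat balance.** In the small-bolus limit the steady state satisfies
Σᵢ ασ,ᵢ cᵢ(0) / (Σσ′ ασ′,ᵢ ρσ′(0)) = c0/ρ0 for every species; residuals are
reported relative to c0/ρ0. The balance is a first-order expansion whose
error is of order c0/ρ0 (growth within a batch) as well as c0/K, so it is
meaningful only when the bolus is small relative to *both* the Monod
constant and the inoculum density. Numerically the residual of a converged
steady state scales linearly in c0/ρ0: about 3.7e-3 at c0/K = 1e-4 with
ρ0/K = 1e-3 and supply (0.4, 0.6), dropping to 3.8e-4 at ρ0/K = 1e-2. The
correspondence test therefore runs at ρ0/K = 1e-2 — still deep in the
ρ0 ≪ K regime where remapping is active — rather than at ρ0/K = 1e-3.

**Remapped boundaries.** The coexistence boundary of a strategy is the
supply composition at which all nutrients are equally valuable over one
batch of the lone resident inoculated at ρ0 (a single species reaches its
serial-dilution steady state in one batch). "Equally valuable" is the
equal yield-weighted Monod-integral condition Yᵢ Iᵢ = const, which makes
the fold increase exp(Σ αᵢYᵢIᵢ) identical for every unit-budget strategy;
for unit yields it reduces to equal Monod integrals. For two nutrients the
imbalance Y₁I₁ − Y₂I₂ is monotone in the first supply fraction and is
solved by Brent's method on [1e-12, 1−1e-12] with composition tolerance
1e-10; a specialist cannot deplete the nutrient it ignores and its boundary
is taken to be its simplex vertex. For p > 2 the pairwise equal-value
conditions are solved by multidimensional root-finding started from the
strategy itself.

**Convex hull and invasion.** Hull membership on the simplex is an interval
test for p = 2 (signed margin in composition units) and a linear
feasibility problem for convex-combination weights for p ≥ 3 (the margin is
then computed from Qhull facet equations when the point cloud is
non-degenerate). Boundary points count as contained. Invasion fitness of an
infinitesimal invader is exp(α⃗inv · Y⃗I⃗) evaluated on the resident
steady-state batch; it matches co-simulation of an invader at relative
abundance 1e-9 to better than 1e-6 on the log-fold, and invasion requires
exceeding the residents' common fold (ρ0 + consumable)/ρ0.

## Sweeps and study conditions

The sweep layer reproduces the model's standard study conditions as tables:
21 equally spaced strategies, equal initial inocula, a log-spaced c0 grid
(default 25 points over c0/K ∈ [1e-4, 1e4], spanning both asymptotic
regimes and the c0 ≈ K diversity minimum), and six supply compositions
with first-nutrient fractions {0.05, 0.1, 0.2, 0.3, 0.4, 0.5} (plus
mirrored fractions for the variants that break the nutrient symmetry).
Variant presets change one assumption at a time: K = (1e-3, 1) with ρ0 = 1;
Y = (10, 1) with ρ0 = 1 and yield-normalized compositions; bitrophic
cross-feeding with γ = f₁/(1−f₁) so that nutrient 1's share of total
nutrient is f₁; bottlenecks of 1008/958/50 cells, optionally with ε = 0.1
budget noise (three seeds per grid point, mean and range reported).
Crossing the full default grid to convergence is expensive; tests and the
worked examples use coarse grids (three points suffice for the U-shape) —
a problem-size choice, documented here, that does not change any model
parameter.

Two properties are verified at deliberately scaled conditions. The
unequal-affinity "reversed" trend (diversity increasing with c0 when the
low-K nutrient is scarce) is tested at ρ0/K₂ = 1e-3 rather than the
canonical ρ0 = K₂ = 1, because the number of batches to steady state grows
like ρ0/c0 and the canonical chemostat-limit point would need ~10⁶
batches; the trend is unambiguous at the scaled inoculum (m_e rises from
4.1 to 10.7 between c0 = 1e-4 and c0 = 3e-2). The unequal-yield monotone
decline is tested at the canonical ρ0 = 1 over the top c0 decade, where
convergence is fast.

## What the synthetic communities do and do not show

All inputs are generated in code: strategy grids, random communities
(Dirichlet allocations), random environments, and budget-noise draws
through one explicitly passed seeded generator (no global RNG state).
These communities capture the model's structure — trade-off-constrained
Monod consumers on a shared nutrient pool — but not features of real
communities such as species-specific yields on the same nutrient,
regulation of enzyme expression, nutrient classes, pH or inhibitor
interactions, or evolutionary change. Passing tests therefore validate the
mathematical behavior of the model and its implementation, not predictions
about any particular microbial system.

## Numerical choices and limitations

* Integrator LSODA, rtol 1e-10 / atol 1e-14; halving the tolerances moves
  final densities by < 1e-6 relative.
* Depletion threshold 1e-9 of total supplied nutrient; batch time capped at
  1e12 (an un-depletable configuration, e.g. a pure specialist facing only
  the other nutrient, raises an integration error carrying the last state).
* Root-finding tolerances: 1e-10 on compositions, residual check 1e-8.
* Steady-state tolerance 1e-8 sustained for 3 batches by default (see
  above for the resolution floor); sweep presets use a 5000-batch cap as
  their problem-size choice.
* Near the coexistence/exclusion transition convergence slows critically;
  results there carry converged=False and a contraction-factor estimate
  rather than a silently truncated answer.
* The p > 2 remapping solver and the hull margin for degenerate point
  clouds are best-effort; the two-nutrient paths are the thoroughly
  validated ones.
* The equal-value (remapping) condition under unequal yields is the
  Y-weighted Monod-integral condition; it reproduces all limiting
  behaviors but other weightings are conceivable, and the coexistence
  region for p > 2 is approximated by the hull of remapped boundary points.
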