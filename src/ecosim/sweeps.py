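"""Parameter sweeps: steady-state diversity as a function of bolus size
across supply compositions and model variants, as tabular output.

Each grid point (bolus size, supply composition) is an independent run of
the serial-dilution protocol for a community of equally spaced strategies
with equal initial inocula; the result rows carry the effective number of
species together with the full abundance vector, so every summary can be
recomputed from its own row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import effective_species
from .errors import EcosimError, ValidationError
from .model import (
    Environment,
    StrategySet,
    make_equally_spaced_strategies,
    sample_budget_noise,
    yield_normalized_supply,
)
from .protocol import (
    BottleneckConfig,
    bolus_schedule,
    run_stochastic,
    run_to_steady_state,
)

__all__ = ["SweepSpec", "run_sweep", "fixture_configs"]

VARIANTS = ("baseline", "unequal_K", "unequal_Y", "crossfeed", "stochastic",
            "alternating")


@dataclass
class SweepSpec:
    """Specification of a diversity-versus-bolus-size sweep.

    ``compositions`` lists nominal first-nutrient supply fractions.  For the
    ``crossfeed`` variant a composition ``f1`` is realized by supplying only
    nutrient 2 with conversion fraction ``gamma = f1 / (1 - f1)``, so that
    nutrient 1's share of the total consumable nutrient is ``f1``.  With
    ``yield_normalized`` the compositions are stated in yield units and
    converted to concentration fractions via ``f_i / Y_i`` renormalized.
    """

    c0_grid: np.ndarray
    compositions: Sequence[float]
    variant: str = "baseline"
    n_strategies: int = 21
    K: float | Sequence[float] = 1.0
    Y: Optional[Sequence[float]] = None
    rho0: float = 1e-3
    epsilon: float = 0.0
    seed: int = 0
    yield_normalized: bool = False
    bottleneck: Optional[BottleneckConfig] = None
    n_batches: int = 200
    burn_in: Optional[int] = None
    n_seeds: int = 3
    cycle_length: int = 2
    steady_state_tol: float = 1e-8
    max_batches: int = 5000

    def __post_init__(self):
        self.c0_grid = np.atleast_1d(np.asarray(self.c0_grid, dtype=float))
        if self.c0_grid.size == 0 or len(self.compositions) == 0:
            raise ValidationError("c0_grid and compositions must be non-empty")
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant == "stochastic" and self.bottleneck is None:
            raise ValidationError("stochastic variant requires a BottleneckConfig")

    def build_strategies(self) -> StrategySet:
        strategies = make_equally_spaced_strategies(self.n_strategies)
        if self.epsilon > 0:
            strategies, _ = sample_budget_noise(strategies, self.epsilon,
                                                np.random.default_rng(self.seed))
        return strategies


def _point_env(spec: SweepSpec, f1: float, c0: float) -> tuple[Environment, float]:
    """Environment and effective gamma for one grid point."""
    gamma = 0.0
    if spec.variant == "crossfeed":
        if not 0 <= f1 < 1:
            raise ValidationError("crossfeed composition must satisfy 0 <= f1 < 1")
        gamma = f1 / (1.0 - f1)
        supply = np.array([0.0, 1.0])
    else:
        supply = np.array([f1, 1.0 - f1])
        if spec.yield_normalized:
            Y = np.ones(2) if spec.Y is None else np.asarray(spec.Y, dtype=float)
            supply = yield_normalized_supply(supply, Y)
    env = Environment(c0=c0, supply_fraction=supply, K=spec.K, Y=spec.Y,
                      byproduct=np.array([[0.0, gamma], [0.0, 0.0]]),
                      rho0=spec.rho0)
    return env, gamma


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep and return one row per (c0, composition) grid point.

    Rows record convergence diagnostics, the effective number of species,
    and per-species abundances (relative to ``rho0``).  Failures at a grid
    point are recorded in the ``error`` column; the sweep continues.
    Results do not depend on the order of grid points.
    """
    strategies = spec.build_strategies()
    m = strategies.n_species
    inoc = np.ones(m) / m
    K_ref = float(np.max(spec.K))
    rows = []
    for f1 in spec.compositions:
        for c0 in spec.c0_grid:
            row = {
                "variant": spec.variant,
                "composition": float(f1),
                "c0": float(c0),
                "c0_over_K": float(c0) / K_ref,
                "gamma": 0.0,
                "converged": False,
                "batches_used": 0,
                "m_e": np.nan,
                "m_e_min": np.nan,
                "m_e_max": np.nan,
                "error": "",
            }
            try:
                env, gamma = _point_env(spec, float(f1), float(c0))
                row["gamma"] = gamma
                if spec.variant == "stochastic":
                    _run_stochastic_point(spec, strategies, env, inoc, row)
                else:
                    schedule = None
                    if spec.variant == "alternating":
                        schedule = bolus_schedule(env, "alternating", spec.cycle_length)
                    res = run_to_steady_state(
                        inoc, strategies, env,
                        steady_state_tol=spec.steady_state_tol,
                        max_batches=spec.max_batches, schedule=schedule)
                    frac = res.rho_star / spec.rho0
                    row.update(converged=res.converged, batches_used=res.batches_used,
                               m_e=effective_species(frac).m_e)
                    for lab, v in zip(strategies.labels, frac):
                        row[f"rho_{lab}"] = v
            except EcosimError as err:
                row["error"] = str(err)
            rows.append(row)
    return pd.DataFrame(rows)


def _run_stochastic_point(spec, strategies, env, inoc, row):
    mes, fracs = [], []
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_seeds)
    for ss in child_seeds:
        res = run_stochastic(inoc, strategies, env, spec.bottleneck,
                             n_batches=spec.n_batches, burn_in=spec.burn_in,
                             rng=np.random.default_rng(ss))
        mes.append(res.diversity().m_e)
        fracs.append(res.mean_fractions)
    mean_frac = np.mean(fracs, axis=0)
    mean_frac = mean_frac / mean_frac.sum()
    row.update(converged=True, batches_used=spec.n_batches * spec.n_seeds,
               m_e=float(np.mean(mes)), m_e_min=float(np.min(mes)),
               m_e_max=float(np.max(mes)))
    for lab, v in zip(strategies.labels, mean_frac):
        row[f"rho_{lab}"] = v


def fixture_configs() -> dict[str, SweepSpec]:
    """Canonical sweep presets for the model's standard study conditions.

    All presets use 21 equally spaced two-nutrient strategies with equal
    initial inocula.  The baseline community has equal Monod constants and
    unit yields with inoculum density ``rho0/K = 1e-3``; the variant
    presets change one assumption at a time: strongly unequal affinities
    ``K = (1e-3, 1)`` with ``rho0 = 1``, unequal yields ``Y = (10, 1)``
    with ``rho0 = 1`` (compositions stated in yield units), a bitrophic
    food web where nutrient 1 exists only as a byproduct of consuming
    nutrient 2, and finite-population bottlenecks of 1008 cells per
    dilution with a 50-cell spike-in from a uniform 21-species pool
    (optionally with a 10% standard deviation in enzyme budgets).
    """
    grid = np.logspace(-4, 4, 25)
    half = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
    both = half + [0.6, 0.7, 0.8, 0.9, 0.95]
    pool = np.full(21, 1.0 / 21)
    bneck = BottleneckConfig(n_cells=1008, n_spikein=50, pool_fractions=pool)
    return {
        "baseline": SweepSpec(c0_grid=grid, compositions=half),
        "unequal_affinity": SweepSpec(c0_grid=grid, compositions=both,
                                      variant="unequal_K", K=(1e-3, 1.0), rho0=1.0),
        "unequal_yield": SweepSpec(c0_grid=grid, compositions=both,
                                   variant="unequal_Y", Y=(10.0, 1.0), rho0=1.0,
                                   yield_normalized=True),
        "crossfeed": SweepSpec(c0_grid=grid, compositions=half, variant="crossfeed"),
        "bottleneck": SweepSpec(c0_grid=grid, compositions=half, variant="stochastic",
                                bottleneck=bneck),
        "bottleneck_noisy_budget": SweepSpec(c0_grid=grid, compositions=half,
                                             variant="stochastic", bottleneck=bneck,
                                             epsilon=0.1),
        "alternating": SweepSpec(c0_grid=grid, compositions=[0.5],
                                 variant="alternating", cycle_length=2),
    }
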