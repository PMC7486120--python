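"""Serial-dilution protocols: chaining batches with deterministic or
stochastic bottlenecks.

The deterministic protocol renormalizes the end-of-batch biomass back to a
fixed inoculum density ``rho0`` and repeats until the inoculum composition
stops changing ('steady state').  At steady state every species grows by
the same factor ``(rho0 + c0) / rho0`` within a batch, so dilution maps the
inoculum onto itself.

The stochastic protocol instead draws a finite number of cells at each
dilution: residents are sampled without replacement (multivariate
hypergeometric) from the final population, optionally topped up with a
'spike-in' of cells drawn from a fixed global pool — a migration term in
the island-biogeography spirit that prevents sampling-driven extinctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .batch import BatchResult, IntegrationOptions, run_batch
from .diversity import DiversitySummary, effective_species
from .errors import IntegrationError, ProtocolError, ValidationError
from .model import Environment, StrategySet

__all__ = [
    "SteadyStateResult",
    "BottleneckConfig",
    "StochasticResult",
    "dilute",
    "run_to_steady_state",
    "bottleneck_sample",
    "run_stochastic",
    "bolus_schedule",
]

#: species with relative abundance below this are treated as numerically absent
ABUNDANCE_FLOOR = 1e-10


def dilute(batch: BatchResult, rho0: float) -> np.ndarray:
    """Inoculum for the next batch: final biomass renormalized to ``rho0``."""
    total = batch.rho_final.sum()
    if not total > 0:
        raise ValidationError("cannot dilute a batch with zero total biomass")
    if rho0 <= 0:
        raise ValidationError("rho0 must be positive")
    return rho0 * (batch.rho_final / total)


@dataclass
class SteadyStateResult:
    """Result of iterating batches to (or toward) steady state.

    ``convergence_rate`` is the estimated per-batch geometric contraction
    factor of the inoculum-composition change (values < 1 mean the
    iteration is contracting).  ``survivors`` marks species that are not in
    sustained geometric decline; at a declared steady state these are the
    coexisting species.
    """

    rho_star: np.ndarray
    batches_used: int
    converged: bool
    convergence_rate: float
    survivors: np.ndarray
    final_batch: BatchResult = field(repr=False)
    per_batch_history: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_survivors(self) -> int:
        return int(self.survivors.sum())

    def diversity(self, survivors_only: bool = False) -> DiversitySummary:
        rho = self.rho_star.copy()
        if survivors_only:
            rho = np.where(self.survivors, rho, 0.0)
        return effective_species(rho)


def _classify_survivors(frac_hist: list[np.ndarray], window: int = 10,
                        fold_tol: float = 1e-6,
                        abundance_floor: float = ABUNDANCE_FLOOR) -> np.ndarray:
    """A species survives if its relative abundance is above the floor and
    it is not declining geometrically over the last ``window`` batches."""
    now = frac_hist[-1]
    alive = now > abundance_floor
    if len(frac_hist) > window:
        then = frac_hist[-1 - window]
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(then > 0, (now / np.maximum(then, 1e-300)) ** (1.0 / window), 0.0)
        alive &= fold >= 1.0 - fold_tol
    return alive


def run_to_steady_state(inoculum0, strategies: StrategySet, env: Environment, *,
                        steady_state_tol: float = 1e-8,
                        sustain: int = 3,
                        max_batches: int = 100_000,
                        options: IntegrationOptions | None = None,
                        schedule: np.ndarray | None = None,
                        record_history: bool = False,
                        survivor_window: int = 10,
                        survivor_fold_tol: float = 1e-6) -> SteadyStateResult:
    """Iterate batch growth and dilution until the inoculum composition
    stops changing.

    Convergence is declared when the maximum per-species relative change of
    the inoculum over one batch (one full cycle if a multi-batch bolus
    ``schedule`` is given) stays below ``steady_state_tol`` for ``sustain``
    consecutive batches.  Species whose relative abundance has fallen below
    ``ABUNDANCE_FLOOR`` are excluded from the convergence criterion, since
    a species in geometric decline never stops changing in relative terms.
    Per-batch composition changes cannot be resolved below the integrator's
    accuracy (~1e-9 relative at the default tolerances), which sets a floor
    on usable values of ``steady_state_tol``; the default stays safely
    above it.

    If ``max_batches`` is reached first the result carries
    ``converged=False`` together with the estimated contraction factor.
    """
    x = np.asarray(inoculum0, dtype=float)
    if np.any(x < 0) or x.sum() <= 0:
        raise ValidationError("inoculum must be non-negative with positive sum")
    x = env.rho0 * x / x.sum()

    sched = np.asarray(schedule, dtype=float) if schedule is not None else None
    cycle = 1 if sched is None else sched.shape[0]

    frac_hist: list[np.ndarray] = [x / env.rho0]
    history = [x.copy()] if record_history else None
    deltas: list[float] = []
    ok_streak = 0
    converged = False
    batch = None
    b = 0
    while b < max_batches:
        env_b = env if sched is None else env.with_supply(sched[b % cycle])
        try:
            batch = run_batch(x, strategies, env_b, options)
        except IntegrationError as err:
            raise IntegrationError(f"integration failed in batch {b}: {err}",
                                   t=err.t, state=err.state) from err
        x = dilute(batch, env.rho0)
        b += 1
        frac = x / env.rho0
        frac_hist.append(frac)
        if len(frac_hist) > max(survivor_window, cycle) + 2:
            frac_hist.pop(0)
        if history is not None:
            history.append(x.copy())
        if b % cycle == 0 and len(frac_hist) > cycle:
            prev = frac_hist[-1 - cycle]
            live = (frac > ABUNDANCE_FLOOR) | (prev > ABUNDANCE_FLOOR)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(frac - prev) / np.maximum(prev, 1e-300)
            delta = float(rel[live].max()) if live.any() else 0.0
            deltas.append(delta)
            if delta < steady_state_tol:
                ok_streak += 1
                if ok_streak >= sustain or delta == 0.0 or strategies.n_species == 1:
                    converged = True
                    break
            else:
                ok_streak = 0

    rate = _estimate_contraction(deltas)
    survivors = _classify_survivors(frac_hist, window=min(survivor_window, len(frac_hist) - 1) or 1,
                                    fold_tol=survivor_fold_tol)
    return SteadyStateResult(
        rho_star=x, batches_used=b, converged=converged, convergence_rate=rate,
        survivors=survivors, final_batch=batch,
        per_batch_history=np.asarray(history) if history is not None else None)


def _estimate_contraction(deltas: Sequence[float]) -> float:
    """Geometric contraction factor from the tail of the delta sequence."""
    tail = [d for d in deltas[-8:] if d > 0]
    if len(tail) < 2:
        return 0.0
    ratios = np.array(tail[1:]) / np.array(tail[:-1])
    return float(np.exp(np.mean(np.log(np.clip(ratios, 1e-16, 1e16)))))


@dataclass
class BottleneckConfig:
    """Finite-cell dilution: ``n_cells`` total per inoculum, of which
    ``n_spikein`` are drawn from a fixed global pool (migration) and the
    rest sampled without replacement from the previous batch."""

    n_cells: int
    n_spikein: int = 0
    pool_fractions: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValidationError("n_cells must be positive")
        if not 0 <= self.n_spikein <= self.n_cells:
            raise ValidationError("need 0 <= n_spikein <= n_cells")
        if self.pool_fractions is not None:
            self.pool_fractions = np.asarray(self.pool_fractions, dtype=float)
            if np.any(self.pool_fractions < 0) or abs(self.pool_fractions.sum() - 1.0) > 1e-12:
                raise ValidationError("pool_fractions must be non-negative and sum to 1")
        elif self.n_spikein > 0:
            raise ValidationError("spike-in requires pool_fractions")


def bottleneck_sample(batch: BatchResult, config: BottleneckConfig,
                      env: Environment,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw the next inoculum as integer cell counts.

    Final biomass is converted to cells with mass quantum ``rho0 /
    n_cells`` (fractional cells resolved by stochastic rounding), then
    ``n_cells - n_spikein`` resident cells are drawn without replacement
    (multivariate hypergeometric) and ``n_spikein`` migrant cells
    multinomially from the pool.  Returned counts sum to ``n_cells``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    quantum = env.rho0 / config.n_cells
    cells_frac = batch.rho_final / quantum
    cells = np.floor(cells_frac).astype(np.int64)
    cells += rng.random(cells.size) < (cells_frac - cells)
    n_resident = config.n_cells - config.n_spikein
    if cells.sum() < n_resident:
        raise ProtocolError(
            f"final population ({int(cells.sum())} cells) too small to draw "
            f"{n_resident} resident cells")
    resident = rng.multivariate_hypergeometric(cells, n_resident, method="marginals")
    counts = resident.astype(np.int64)
    if config.n_spikein > 0:
        counts = counts + rng.multinomial(config.n_spikein, config.pool_fractions)
    return counts


@dataclass
class StochasticResult:
    """Time series and post-burn-in averages of a stochastic run."""

    mean_fractions: np.ndarray
    me_series: np.ndarray
    counts_history: np.ndarray
    burn_in: int

    def diversity(self) -> DiversitySummary:
        """Effective species of the batch-averaged composition."""
        return effective_species(self.mean_fractions)


def run_stochastic(inoculum0, strategies: StrategySet, env: Environment,
                   config: BottleneckConfig, n_batches: int,
                   burn_in: int | None = None,
                   options: IntegrationOptions | None = None,
                   rng: np.random.Generator | int | None = None) -> StochasticResult:
    """Run ``n_batches`` growth cycles with finite-cell bottlenecks.

    Reports per-species inoculum fractions averaged over the post-burn-in
    batches (default burn-in: half the run) and the per-batch effective
    number of species.  Fully reproducible given a seed.
    """
    if burn_in is None:
        burn_in = n_batches // 2
    if not 0 <= burn_in < n_batches:
        raise ValidationError("need 0 <= burn_in < n_batches")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(config.seed if rng is None else rng)
    x = np.asarray(inoculum0, dtype=float)
    if np.any(x < 0) or x.sum() <= 0:
        raise ValidationError("inoculum must be non-negative with positive sum")
    x = env.rho0 * x / x.sum()
    quantum = env.rho0 / config.n_cells

    m = strategies.n_species
    counts_history = np.zeros((n_batches, m), dtype=np.int64)
    me_series = np.zeros(n_batches)
    for b in range(n_batches):
        batch = run_batch(x, strategies, env, options)
        counts = bottleneck_sample(batch, config, env, rng)
        counts_history[b] = counts
        me_series[b] = effective_species(counts.astype(float)).m_e
        x = counts * quantum
    frac = counts_history[burn_in:] / config.n_cells
    return StochasticResult(mean_fractions=frac.mean(axis=0), me_series=me_series,
                            counts_history=counts_history, burn_in=burn_in)


def bolus_schedule(env: Environment, schedule: str,
                   cycle_length: int | None = None) -> np.ndarray:
    """Per-batch supply compositions for seasonal bolus schedules.

    ``"mixed"`` supplies the environment's composition every batch.
    ``"alternating"`` supplies one pure nutrient per batch, cycling over
    ``cycle_length`` batches so that the long-run proportions equal
    ``env.supply_fraction`` (which must be representable by the cycle
    length).  Returns an array of shape ``(cycle, p)``.
    """
    f = env.supply_fraction
    if schedule == "mixed":
        return f[None, :].copy()
    if schedule != "alternating":
        raise ValidationError("schedule must be 'mixed' or 'alternating'")
    if cycle_length is None or cycle_length < 1:
        raise ValidationError("alternating schedule requires a positive cycle_length")
    counts = f * cycle_length
    if np.any(np.abs(counts - np.round(counts)) > 1e-9):
        raise ValidationError(
            f"supply proportions {f.tolist()} are not representable by a "
            f"cycle of length {cycle_length}")
    # Bresenham-style spreading: each step, feed the nutrient most in deficit.
    credit = np.zeros(env.p)
    seq = np.zeros((cycle_length, env.p))
    remaining = np.round(counts).astype(int)
    for b in range(cycle_length):
        credit += f
        order = np.argsort(-credit, kind="stable")
        i = next(i for i in order if remaining[i] > 0)
        seq[b, i] = 1.0
        credit[i] -= 1.0
        remaining[i] -= 1
    return seq
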