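"""Core domain types: enzyme-allocation strategies, nutrient environments,
and the Monod uptake law.

A community is a set of species, each defined by how it apportions a fixed
enzyme budget ``E`` across ``p`` substitutable nutrients.  Species ``s``
consumes nutrient ``i`` at a per-biomass rate

    j[s, i] = alpha[s, i] * c[i] / (K[i] + c[i]),

where ``alpha[s, i]`` is the enzyme allocation and ``K[i]`` the Monod
half-saturation constant.  The trade-off constraint is that each row of
``alpha`` sums to ``E + epsilon * xi[s]`` with ``xi`` standard-normal draws
(``epsilon = 0`` gives exact trade-offs and places every strategy on the
unit simplex).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError

#: tolerance on |row_sum - budget| when validating a strategy set
ROW_SUM_TOL = 1e-9

__all__ = [
    "StrategySet",
    "Environment",
    "CommunityState",
    "make_equally_spaced_strategies",
    "sample_budget_noise",
    "uptake_rates",
    "yield_normalized_supply",
    "ROW_SUM_TOL",
]


def _as_float_array(x, name, ndim):
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class StrategySet:
    """A community's enzyme-allocation matrix with (possibly noisy) budgets.

    Parameters
    ----------
    alpha : (m, p) array
        Non-negative enzyme allocations; rows are species, columns nutrients.
    budget : float
        Mean total enzyme budget ``E`` (default 1).
    epsilon : float
        Standard deviation of the species-specific budget perturbation.
    xi : (m,) array, optional
        The sampled standard-normal budget draws; zeros when ``epsilon`` is 0.
    labels : list of str, optional
        Species identifiers; defaults to ``s00, s01, ...``.
    """

    alpha: np.ndarray
    budget: float = 1.0
    epsilon: float = 0.0
    xi: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self):
        self.alpha = _as_float_array(self.alpha, "alpha", 2)
        m, p = self.alpha.shape
        if m < 1 or p < 1:
            raise ValidationError("alpha must have at least one row and one column")
        if self.xi is None:
            self.xi = np.zeros(m)
        self.xi = _as_float_array(self.xi, "xi", 1)
        if self.xi.shape != (m,):
            raise ValidationError(f"xi must have length {m}")
        if self.labels is None:
            self.labels = [f"s{k:02d}" for k in range(m)]
        if len(self.labels) != m:
            raise ValidationError(f"labels must have length {m}")
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self):
        if self.budget <= 0:
            raise ValidationError("budget must be positive")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be non-negative")
        if np.any(self.alpha < 0):
            raise ValidationError("alpha entries must be non-negative")
        sums = self.alpha.sum(axis=1)
        if np.any(sums <= 0):
            raise ValidationError("every strategy row must have a positive sum")
        expect = self.budgets
        bad = np.abs(sums - expect) > ROW_SUM_TOL
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ValidationError(
                f"row {k} sums to {sums[k]!r} but its budget is {expect[k]!r} "
                f"(|diff| > {ROW_SUM_TOL})"
            )

    @property
    def n_species(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_nutrients(self) -> int:
        return self.alpha.shape[1]

    @property
    def budgets(self) -> np.ndarray:
        """Per-species total enzyme budgets ``E + epsilon * xi``."""
        return self.budget + self.epsilon * self.xi

    @property
    def fractions(self) -> np.ndarray:
        """Strategies normalized to the simplex (rows sum to 1)."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "budget": self.budget,
            "epsilon": self.epsilon,
            "xi": self.xi.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrategySet":
        return cls(
            alpha=np.asarray(d["alpha"], dtype=float),
            budget=float(d.get("budget", 1.0)),
            epsilon=float(d.get("epsilon", 0.0)),
            xi=None if d.get("xi") is None else np.asarray(d["xi"], dtype=float),
            labels=d.get("labels"),
        )

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "StrategySet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Environment:
    """Nutrient environment of a single batch.

    Parameters
    ----------
    c0 : float
        Total nutrient concentration supplied at the start of a batch.
    supply_fraction : (p,) array
        Composition of the bolus, ``c_i(0) / c0``; sums to 1.
    K : (p,) array or float
        Monod half-saturation constants.
    Y : (p,) array or float, optional
        Biomass yield per unit of nutrient ``i`` (default 1 for all).
    byproduct : (p, p) array, optional
        Conversion matrix ``G[i, i']``: consuming one unit of nutrient
        ``i'`` releases ``G[i, i']`` units of nutrient ``i``.  Zero matrix
        (default) disables cross-feeding; the diagonal must be zero.
    rho0 : float
        Total inoculum biomass density at the start of each batch.
    """

    c0: float
    supply_fraction: np.ndarray
    K: np.ndarray
    Y: np.ndarray | None = None
    byproduct: np.ndarray | None = None
    rho0: float = 1e-3

    def __post_init__(self):
        self.supply_fraction = _as_float_array(self.supply_fraction, "supply_fraction", 1)
        p = self.supply_fraction.size
        self.K = np.broadcast_to(np.asarray(self.K, dtype=float), (p,)).copy()
        if self.Y is None:
            self.Y = np.ones(p)
        self.Y = np.broadcast_to(np.asarray(self.Y, dtype=float), (p,)).copy()
        if self.byproduct is None:
            self.byproduct = np.zeros((p, p))
        self.byproduct = _as_float_array(self.byproduct, "byproduct", 2)
        self.validate()

    def validate(self):
        p = self.p
        if self.c0 <= 0:
            raise ValidationError("c0 must be positive")
        if self.rho0 <= 0:
            raise ValidationError("rho0 must be positive")
        if np.any(self.supply_fraction < 0):
            raise ValidationError("supply_fraction entries must be non-negative")
        if abs(self.supply_fraction.sum() - 1.0) > 1e-12:
            raise ValidationError("supply_fraction must sum to 1 within 1e-12")
        if np.any(self.K <= 0) or np.any(self.Y <= 0):
            raise ValidationError("K and Y must be strictly positive")
        if self.byproduct.shape != (p, p):
            raise ValidationError(f"byproduct must be {p}x{p}")
        if np.any(self.byproduct < 0):
            raise ValidationError("byproduct entries must be non-negative")
        if np.any(np.diag(self.byproduct) != 0):
            raise ValidationError("byproduct diagonal must be zero")

    @property
    def p(self) -> int:
        return self.supply_fraction.size

    @property
    def c_init(self) -> np.ndarray:
        """Initial nutrient concentrations ``c0 * supply_fraction``."""
        return self.c0 * self.supply_fraction

    @property
    def gamma_scalar(self) -> float:
        """The scalar conversion fraction of the canonical two-nutrient
        cross-feeding matrix ``[[0, G], [0, 0]]``; raises if the matrix is
        not of that form."""
        if self.p != 2 or self.byproduct[1, 0] != 0:
            raise ValidationError("byproduct matrix is not the 2-nutrient [[0,G],[0,0]] form")
        return float(self.byproduct[0, 1])

    @classmethod
    def two_nutrient(cls, c0, f1, *, K=1.0, Y=None, gamma=0.0, rho0=1e-3) -> "Environment":
        """Convenience constructor for the two-nutrient case.

        ``f1`` is the supply fraction of nutrient 1; ``gamma`` builds the
        byproduct matrix ``[[0, gamma], [0, 0]]`` (nutrient 2 consumption
        releases nutrient 1).
        """
        by = np.array([[0.0, float(gamma)], [0.0, 0.0]])
        return cls(c0=c0, supply_fraction=np.array([f1, 1.0 - f1]), K=K, Y=Y,
                   byproduct=by, rho0=rho0)

    def with_supply(self, supply_fraction) -> "Environment":
        return replace(self, supply_fraction=np.asarray(supply_fraction, dtype=float))

    def with_c0(self, c0) -> "Environment":
        return replace(self, c0=float(c0))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "c0": self.c0,
            "supply_fraction": self.supply_fraction.tolist(),
            "K": self.K.tolist(),
            "Y": self.Y.tolist(),
            "byproduct": self.byproduct.tolist(),
            "rho0": self.rho0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(
            c0=float(d["c0"]),
            supply_fraction=np.asarray(d["supply_fraction"], dtype=float),
            K=np.asarray(d["K"], dtype=float),
            Y=None if d.get("Y") is None else np.asarray(d["Y"], dtype=float),
            byproduct=None if d.get("byproduct") is None else np.asarray(d["byproduct"], dtype=float),
            rho0=float(d.get("rho0", 1e-3)),
        )

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "Environment":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CommunityState:
    """Instantaneous state of a batch: biomass densities, nutrient
    concentrations and elapsed time."""

    rho: np.ndarray
    c: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.rho = _as_float_array(self.rho, "rho", 1)
        self.c = _as_float_array(self.c, "c", 1)
        if np.any(self.rho < 0) or np.any(self.c < 0):
            raise ValidationError("rho and c must be entrywise non-negative")
        if self.t < 0:
            raise ValidationError("t must be non-negative")

    def uptake(self, strategies: StrategySet, env: Environment) -> np.ndarray:
        return uptake_rates(self, strategies, env)


def make_equally_spaced_strategies(m: int, p: int = 2) -> StrategySet:
    """Build ``m`` equally spaced exact-trade-off strategies on the
    ``p``-nutrient simplex.

    For two nutrients the first-nutrient allocations are
    ``0, 1/(m-1), ..., 1`` (both specialists included).  For ``p > 2`` the
    strategies form the regular simplex lattice with ``m`` nodes per edge:
    all allocations ``(k_1, ..., k_p) / (m - 1)`` with non-negative integer
    ``k`` summing to ``m - 1`` (``binom(m+p-2, p-1)`` strategies in total).
    """
    if m < 2:
        raise ValidationError("m must be at least 2 (spacing is undefined otherwise)")
    if p < 2:
        raise ValidationError("p must be at least 2")
    if p == 2:
        x = np.linspace(0.0, 1.0, m)
        alpha = np.column_stack([x, 1.0 - x])
    else:
        combos = [k for k in itertools.product(range(m), repeat=p) if sum(k) == m - 1]
        combos.sort(reverse=True)
        alpha = np.asarray(combos, dtype=float) / (m - 1)
    return StrategySet(alpha=alpha)


def sample_budget_noise(strategies: StrategySet, epsilon: float,
                        rng: np.random.Generator | int) -> tuple[StrategySet, int]:
    """Draw species-specific budgets ``E + epsilon * xi`` and rescale a
    strategy set to them.

    Each row is rescaled multiplicatively, preserving allocation fractions.
    ``xi`` are standard-normal draws; a draw giving a non-positive budget is
    rejected and redrawn.  Returns the new strategy set and the number of
    rejected draws.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    m = strategies.n_species
    xi = np.zeros(m)
    n_rejected = 0
    if epsilon > 0:
        xi = rng.standard_normal(m)
        bad = strategies.budget + epsilon * xi <= 0
        while np.any(bad):
            n_rejected += int(bad.sum())
            xi[bad] = rng.standard_normal(int(bad.sum()))
            bad = strategies.budget + epsilon * xi <= 0
    budgets = strategies.budget + epsilon * xi
    alpha = strategies.fractions * budgets[:, None]
    out = StrategySet(alpha=alpha, budget=strategies.budget, epsilon=epsilon,
                      xi=xi, labels=list(strategies.labels))
    return out, n_rejected


def uptake_rates(state: CommunityState, strategies: StrategySet,
                 env: Environment) -> np.ndarray:
    """Per-biomass uptake rates ``j[s, i] = alpha[s, i] * c_i / (K_i + c_i)``."""
    c = np.asarray(state.c, dtype=float)
    if c.size != env.p or strategies.n_nutrients != env.p:
        raise ValidationError("dimension mismatch between state, strategies and environment")
    if np.any(c < 0):
        raise ValidationError("negative nutrient concentration")
    return strategies.alpha * (c / (env.K + c))


def yield_normalized_supply(fractions, Y) -> np.ndarray:
    """Convert a yield-normalized composition to concentration fractions.

    A composition stated 'in units of yield' allocates biomass potential;
    the corresponding concentration fractions are ``(f_i / Y_i)``
    renormalized to sum to 1.
    """
    f = np.asarray(fractions, dtype=float)
    Y = np.broadcast_to(np.asarray(Y, dtype=float), f.shape)
    w = f / Y
    return w / w.sum()
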