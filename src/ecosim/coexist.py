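"""Coexistence analysis: chemostat-limit steady-state balance, invasion
fitness, remapped coexistence boundaries, and the convex-hull criterion.

In the limit of a vanishing bolus (c0 << K) serial dilution reproduces the
chemostat steady state, where supply and consumption balance nutrient by
nutrient.  At finite bolus size the within-batch dynamics shift each
species' coexistence boundary on the nutrient simplex: the boundary of a
strategy is the supply composition for which, over a whole batch, all
nutrients are equally valuable (equal yield-weighted Monod integrals
``Y_i * I_i``), so that any unit-budget strategy invades neutrally.
Coexistence of arbitrarily many species is possible exactly when the
supply lies inside the convex hull of the (remapped) strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, linprog, root

from .batch import BatchResult, IntegrationOptions, run_batch
from .errors import StaleStateError, ValidationError
from .model import Environment, StrategySet

__all__ = [
    "ChemostatView",
    "RemapResult",
    "HullResult",
    "CoexistenceWindow",
    "chemostat_residual",
    "invasion_fold",
    "remapped_boundary",
    "convex_hull_contains",
    "coexistence_window",
]


@dataclass
class ChemostatView:
    """First-order (c0 << K) steady-state balance of a community.

    ``residuals[s]`` is the relative deviation of species ``s`` from the
    supply/consumption balance: zero for every species at a chemostat-limit
    steady state.  ``s_rates`` (average nutrient supply rates ``c_i(0) /
    t_f``) and ``delta_tilde`` (``c0 / (rho0 * t_f)``, the analogue of a
    chemostat dilution rate) are filled when a batch time ``t_f`` is given.
    """

    residuals: np.ndarray
    delta_tilde: Optional[float] = None
    s_rates: Optional[np.ndarray] = None


def chemostat_residual(inoculum, strategies: StrategySet, env: Environment,
                       t_f: float | None = None) -> ChemostatView:
    """Per-species deviation from the chemostat-limit steady-state balance.

    The balance requires, for every species,
    ``sum_i alpha[s,i] * c_i(0) / (sum_s' alpha[s',i] * rho_s'(0)) = c0 / rho0``;
    residuals are reported relative to ``c0 / rho0``.
    """
    if strategies.epsilon != 0:
        raise ValidationError("chemostat balance assumes exact trade-offs (epsilon=0)")
    rho = np.asarray(inoculum, dtype=float)
    if np.any(rho < 0) or rho.sum() <= 0:
        raise ValidationError("inoculum must be non-negative with positive sum")
    alpha = strategies.alpha
    c_init = env.c_init
    denom = alpha.T @ rho                       # community enzyme on each nutrient
    starved = (denom <= 0) & (c_init > 0)
    if np.any(starved):
        raise ValidationError(
            f"no enzyme allocated to supplied nutrient(s) {np.flatnonzero(starved).tolist()}")
    terms = np.where(denom > 0, c_init / np.where(denom > 0, denom, 1.0), 0.0)
    ratio = alpha @ terms                       # per-species supply per inoculum
    target = env.c0 / rho.sum()
    residuals = (ratio - target) / target
    view = ChemostatView(residuals=residuals)
    if t_f is not None:
        if t_f <= 0:
            raise ValidationError("t_f must be positive")
        view.s_rates = c_init / t_f
        view.delta_tilde = env.c0 / (rho.sum() * t_f)
    return view


def invasion_fold(resident_batch: BatchResult, invader, env: Environment,
                  steady_tol: float = 1e-6) -> float:
    """Within-batch fold increase of an infinitesimal invader.

    The invader does not perturb the resident trajectory, so its fold is
    ``exp(sum_i invader_i * Y_i * I_i)`` with the Monod integrals of the
    resident batch.  It can invade iff this exceeds the residents' common
    steady-state fold ``(rho0 + consumable) / rho0``.  Raises
    :class:`StaleStateError` if the resident batch is not at steady state
    (the residents' folds differ beyond ``steady_tol``).
    """
    inv = np.asarray(invader, dtype=float)
    if inv.ndim != 1 or inv.size != env.p:
        raise ValidationError("invader must be an allocation row of length p")
    present = resident_batch.rho_init > 0
    folds = resident_batch.fold[present]
    spread = folds.max() / folds.min() - 1.0
    if spread > steady_tol:
        raise StaleStateError(
            f"resident batch is not at steady state: species folds differ by "
            f"{spread:.3g} (> {steady_tol})")
    return float(np.exp(inv @ (env.Y * resident_batch.I)))


@dataclass
class RemapResult:
    """Remapped coexistence boundary of a single strategy."""

    strategy: np.ndarray
    boundary: np.ndarray
    converged: bool
    residual: float


def _boundary_residual(x, strategy, env, options):
    """Imbalance of nutrient value Y1*I1 - Y2*I2 for a lone resident grown
    on supply composition (x, 1-x)."""
    strat = StrategySet(alpha=strategy[None, :], budget=float(strategy.sum()))
    batch = run_batch(np.array([env.rho0]), strat, env.with_supply([x, 1.0 - x]),
                      options)
    v = env.Y * batch.I
    return v[0] - v[1]


def remapped_boundary(strategy, env: Environment, *, xtol: float = 1e-10,
                      resid_tol: float = 1e-8,
                      options: IntegrationOptions | None = None) -> RemapResult:
    """Supply composition at which all nutrients are equally valuable over
    a batch of the lone resident ``strategy`` inoculated at ``rho0``.

    For two nutrients the equal-value condition ``Y1*I1 = Y2*I2`` is solved
    by bracketed scalar root-finding on the first supply fraction; the
    residual is monotone in the composition, so the root is unique.  A
    specialist (a strategy with a zero allocation) cannot deplete the other
    nutrient, and its boundary is the corresponding simplex vertex.  For
    ``p > 2`` the pairwise equal-value conditions are solved by
    multidimensional root-finding started from the strategy itself.
    """
    strat = np.asarray(strategy, dtype=float)
    if strat.ndim != 1 or strat.size != env.p:
        raise ValidationError("strategy must be an allocation row of length p")
    if np.any(strat < 0) or strat.sum() <= 0:
        raise ValidationError("strategy must be non-negative with positive sum")

    frac = strat / strat.sum()
    if np.any(strat == 0):
        # specialist: boundary sits at the simplex vertex/face of its support
        return RemapResult(strategy=strat, boundary=frac.copy(), converged=True,
                           residual=0.0)

    if env.p == 2:
        lo, hi = 1e-12, 1.0 - 1e-12
        f = lambda x: _boundary_residual(x, strat, env, options)
        f_lo, f_hi = f(lo), f(hi)
        if f_lo == 0.0:
            x_star, converged = lo, True
        elif f_hi == 0.0:
            x_star, converged = hi, True
        elif f_lo * f_hi > 0:
            # not bracketed in the open simplex: boundary at the nearer vertex
            x_star = 0.0 if abs(f_lo) < abs(f_hi) else 1.0
            return RemapResult(strategy=strat,
                               boundary=np.array([x_star, 1.0 - x_star]),
                               converged=False,
                               residual=float(f_lo if x_star == 0.0 else f_hi))
        else:
            x_star = brentq(f, lo, hi, xtol=xtol)
            converged = True
        resid = f(x_star)
        return RemapResult(strategy=strat, boundary=np.array([x_star, 1.0 - x_star]),
                           converged=converged and abs(resid) < resid_tol,
                           residual=float(resid))

    # p > 2: solve the p-1 pairwise differences on the open simplex
    def g(free):
        s = np.append(free, 1.0 - free.sum())
        s = np.clip(s, 1e-12, None)
        s = s / s.sum()
        strat_set = StrategySet(alpha=strat[None, :], budget=float(strat.sum()))
        batch = run_batch(np.array([env.rho0]), strat_set, env.with_supply(s), options)
        v = env.Y * batch.I
        return v[:-1] - v[-1]

    sol = root(g, frac[:-1], method="hybr", tol=xtol)
    free = sol.x
    boundary = np.append(free, 1.0 - free.sum())
    ok = sol.success and np.all(boundary > -1e-9) and boundary.sum() <= 1 + 1e-9
    boundary = np.clip(boundary, 0.0, None)
    boundary = boundary / boundary.sum()
    resid = float(np.max(np.abs(sol.fun)))
    return RemapResult(strategy=strat, boundary=boundary,
                       converged=bool(ok and resid < resid_tol), residual=resid)


@dataclass
class HullResult:
    """Membership of a supply composition in the convex hull of strategies."""

    contains: bool
    weights: Optional[np.ndarray]
    margin: float


def convex_hull_contains(points, supply, tol: float = 1e-12) -> HullResult:
    """Closed-hull membership test on the nutrient simplex.

    ``margin`` is the signed distance to the hull boundary in composition
    units (positive inside, negative outside); for ``p >= 3`` it is
    measured in the simplex coordinates excluding the last component, and
    is NaN if the point cloud is degenerate.  ``weights`` are convex-
    combination weights over the given points reproducing the supply.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    s = np.asarray(supply, dtype=float)
    if pts.shape[1] != s.size:
        raise ValidationError("points and supply have different dimensions")
    n, p = pts.shape

    if p == 2:
        xs = pts[:, 0]
        lo, hi = xs.min(), xs.max()
        margin = float(min(s[0] - lo, hi - s[0]))
        contains = margin >= -tol
        weights = None
        if contains:
            weights = np.zeros(n)
            i_lo, i_hi = int(np.argmin(xs)), int(np.argmax(xs))
            if hi - lo < tol:
                weights[i_lo] = 1.0
            else:
                w = (s[0] - lo) / (hi - lo)
                weights[i_hi] += w
                weights[i_lo] += 1.0 - w
        return HullResult(contains=contains, weights=weights, margin=margin)

    # p >= 3: feasibility of  pts.T @ w = s,  sum w = 1,  w >= 0
    A_eq = np.vstack([pts.T, np.ones(n)])
    b_eq = np.append(s, 1.0)
    res = linprog(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * n,
                  method="highs")
    contains = bool(res.status == 0)
    weights = res.x if contains else None

    margin = np.nan
    try:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts[:, :-1])
        # facet equations A x + b <= 0 inside; signed distance = -max(A x + b)
        vals = hull.equations[:, :-1] @ s[:-1] + hull.equations[:, -1]
        margin = float(-vals.max())
    except Exception:
        pass
    return HullResult(contains=contains, weights=weights, margin=margin)


@dataclass
class CoexistenceWindow:
    """Supply interval (first-nutrient fraction) of mutual invasibility for
    two strategies on two nutrients."""

    lo: float
    hi: float
    result_lo: RemapResult = field(repr=False)
    result_hi: RemapResult = field(repr=False)

    @property
    def empty(self) -> bool:
        return self.lo > self.hi

    def contains(self, f1: float) -> bool:
        return (not self.empty) and self.lo <= f1 <= self.hi


def coexistence_window(species_a, species_b, env: Environment,
                       **kwargs) -> CoexistenceWindow:
    """Mutual-invasibility supply interval of two two-nutrient strategies.

    The remapped boundaries of the two species bracket the interval of
    supplies at which each can invade the other; the window is empty when
    the boundaries cross.  ``species_a`` must allocate less to nutrient 1
    than ``species_b``.
    """
    a = np.asarray(species_a, dtype=float)
    b = np.asarray(species_b, dtype=float)
    if env.p != 2:
        raise ValidationError("coexistence_window is defined for two nutrients")
    if np.allclose(a, b):
        raise ValidationError("identical strategies give a degenerate window")
    if not a[0] < b[0]:
        raise ValidationError("species_a must allocate less to nutrient 1 than species_b")
    ra = remapped_boundary(a, env, **kwargs)
    rb = remapped_boundary(b, env, **kwargs)
    return CoexistenceWindow(lo=float(ra.boundary[0]), hi=float(rb.boundary[0]),
                             result_lo=ra, result_hi=rb)
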