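"""Community diversity summaries.

Diversity of a steady-state community is quantified by the effective number
of species, the exponential of the Shannon entropy of the relative
abundances:

    P_s = rho*_s(0) / rho0,   S = -sum_s P_s ln P_s,   m_e = exp(S).

``m_e`` equals the species count for a uniform community and 1 for a
monoculture; zero-abundance species contribute nothing (x ln x -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["DiversitySummary", "effective_species"]


@dataclass
class DiversitySummary:
    P: np.ndarray
    S: float
    m_e: float


def effective_species(rho_star, rho0: float | None = None) -> DiversitySummary:
    """Shannon diversity and effective number of species of a composition.

    Parameters
    ----------
    rho_star : (m,) array
        Non-negative steady-state abundances.
    rho0 : float, optional
        Total inoculum density; defaults to ``sum(rho_star)``.  Abundances
        are normalized by it to relative abundances ``P``.
    """
    rho = np.asarray(rho_star, dtype=float)
    if rho.ndim != 1 or rho.size == 0:
        raise ValidationError("rho_star must be a non-empty 1-D vector")
    if np.any(rho < 0):
        raise ValidationError("abundances must be non-negative")
    total = rho.sum()
    if total <= 0:
        raise ValidationError("all abundances are zero")
    if rho0 is None:
        rho0 = total
    if rho0 <= 0:
        raise ValidationError("rho0 must be positive")
    if abs(total - rho0) > 1e-6 * rho0:
        raise ValidationError(f"sum(rho_star)={total!r} does not match rho0={rho0!r}")
    P = rho / rho0
    nz = P > 0
    S = float(-(P[nz] * np.log(P[nz])).sum())
    return DiversitySummary(P=P, S=S, m_e=float(np.exp(S)))
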