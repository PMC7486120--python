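"""Exception hierarchy for the simulator."""

from __future__ import annotations


class EcosimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcosimError, ValueError):
    """Invalid argument or inconsistent model state."""


class IntegrationError(EcosimError, RuntimeError):
    """ODE integration failed; carries the last valid state reached.

    Attributes
    ----------
    t : float or None
        Time of the last valid integrator state.
    state : ndarray or None
        Raw state vector at that time.
    """

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class ProtocolError(EcosimError, RuntimeError):
    """A dilution-protocol step could not be carried out."""


class StaleStateError(EcosimError, RuntimeError):
    """A batch result was required to be at steady state but is not."""


class AuditError(EcosimError, RuntimeError):
    """A ledger audit was requested for an unsupported batch result."""
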