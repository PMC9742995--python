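"""Exception types shared across the package."""


class PhytoallocError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhytoallocError, ValueError):
    """An argument is outside its physical domain (e.g. negative nitrate)."""


class InfeasibleParametersError(PhytoallocError, ValueError):
    """A parameter set cannot support a physical allocation state.

    The message names the violated pool or constraint so a user can see
    which quota left the [0, 1] range or which budget cannot close.
    """


class ConsistencyError(PhytoallocError, RuntimeError):
    """An internal balance that should hold by construction was violated."""
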