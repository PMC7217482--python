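"""Exception types used across the package."""


class NeuriceError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeuriceError, ValueError):
    """A parameter value violates a model invariant (rejected, never clamped)."""


class InconsistentMorphologyError(NeuriceError, ValueError):
    """A morphology specification is internally contradictory."""


class UnsupportedMorphologyError(NeuriceError, ValueError):
    """The requested quantity is not defined for this morphology
    (e.g. a trigger point at x > 0 on a synaptically driven dendrite)."""


class ConvergenceError(NeuriceError, RuntimeError):
    """A quadrature or root-finding routine failed to reach its tolerance."""


class BracketError(ConvergenceError):
    """A root could not be bracketed (e.g. an unreachable target firing rate)."""


class StabilityError(NeuriceError, ValueError):
    """The explicit time step exceeds the stability bound of the lattice scheme."""


class MisalignedTriggerError(NeuriceError, ValueError):
    """The trigger position does not coincide with a voltage node of the lattice."""


class NumericalBlowupError(NeuriceError, RuntimeError):
    """A simulated field left the physically plausible range."""
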