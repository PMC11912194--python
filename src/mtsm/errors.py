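"""Exception hierarchy shared by all mtsm modules.

Every error corresponds to a well-defined failure mode of the estimation
workflow (bad input matrix, disconnected chain, singular projection, ...),
so callers and the CLI can map each one to a single-line diagnostic.
"""


class MTSMError(Exception):
    """Base class for all mtsm errors."""


class NotStochastic(MTSMError):
    """A matrix column does not sum to one within tolerance."""


class NegativeEntry(MTSMError):
    """A transition probability is negative beyond tolerance."""


class Disconnected(MTSMError):
    """The chain has more than one closed communicating class."""


class MultipleUnitEigenvalues(Disconnected):
    """More than one eigenvalue of modulus one (disconnected model)."""


class ParseError(MTSMError):
    """A trajectory file contains a non-integer token."""


class EmptyFile(MTSMError):
    """A trajectory file contains no frames."""


class LagTooLong(MTSMError):
    """Some trajectory is shorter than the requested lag."""


class AllDisconnected(MTSMError):
    """No usable strongly connected component in the count graph."""


class InsufficientOrigins(MTSMError):
    """Fewer sliding time origins than the configured minimum."""


class EmptyMacrostate(MTSMError):
    """A macrostate contains no microstates."""


class DimensionMismatch(MTSMError):
    """Vector/matrix dimensions are inconsistent."""


class SingularMatrix(MTSMError):
    """A required matrix inversion failed (ill-conditioned projection)."""


class SeriesTooShort(MTSMError):
    """A transition-matrix series has too few entries."""


class NonInvertible(MTSMError):
    """The linear solve for a memory-kernel slice is singular."""


class ZeroNormalizer(MTSMError):
    """The kernel element used for normalization vanishes."""


class ThresholdNeverMet(MTSMError):
    """The normalized kernel never decays below the threshold."""


class Blowup(MTSMError):
    """GME propagation produced entries far outside [0, 1] (noisy kernel)."""


class LagMismatch(MTSMError):
    """Inconsistent lag times between combined models."""


class TimeNotOnGrid(MTSMError):
    """Requested time is not a multiple of the series time step."""


class GridTooLong(MTSMError):
    """Evaluation grid exceeds the directly countable range."""


class InvalidParams(MTSMError):
    """Toy-model parameters violate their constraints."""
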