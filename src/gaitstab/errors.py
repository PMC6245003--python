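"""Exception hierarchy for the gaitstab pipeline."""


class GaitStabError(Exception):
    """Base class for all gaitstab errors."""


class MissingChannel(GaitStabError):
    """A required marker or analog channel is absent from a trial."""


class BadTimeBase(GaitStabError):
    """The time vector is not uniformly sampled at the declared rate."""


class ValidationError(GaitStabError):
    """Invalid parameters or an invalid trial."""


class TooShort(GaitStabError):
    """A series is too short for the requested operation."""


class NoGaitDetected(GaitStabError):
    """Fewer than two heel strikes found on one side."""


class NonFiniteInput(GaitStabError):
    """NaN or infinite values where finite kinematics are required."""


class InsufficientBaseline(GaitStabError):
    """Not enough consecutive steps to form the baseline summary."""


class TriggerMisaligned(GaitStabError):
    """A perturbation trigger does not coincide with a non-dominant heel strike."""


class WindowOverlap(GaitStabError):
    """Peri-perturbation windows of two events share steps."""


class IncompleteWindow(GaitStabError):
    """A peri-perturbation window is missing post-perturbation steps."""


class InsufficientStrides(GaitStabError):
    """Fewer strides available than the local-dynamic-stability analysis needs."""


class NoNeighbours(GaitStabError):
    """No admissible nearest neighbour outside the Theiler window."""


class InfeasibleProfile(GaitStabError):
    """Perturbation profile constraints cannot be satisfied."""


class ExcursionExceeded(GaitStabError):
    """Cumulative platform excursion would exceed the hardware bound."""
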