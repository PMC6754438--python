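"""Exception hierarchy for the TTM pipeline.

Every stage raises a ``TTMError`` subclass so that batch drivers (the CLI
``process`` command in particular) can log-and-continue per recording while
genuine programming errors still propagate.
"""


class TTMError(Exception):
    """Base class for all pipeline errors."""


class InputError(TTMError, ValueError):
    """Malformed or inconsistent input (shapes, lengths, identifiers)."""


class NumericDomainError(TTMError, ValueError):
    """A value left the numeric domain an operation requires (e.g. F_min <= 0)."""


class InsufficientEventsError(TTMError):
    """Fewer complete paced events were found than are needed for averaging."""


class InterpeakMismatchError(TTMError):
    """Inter-event intervals do not match the pacing period; recording rejected."""


class IncompleteTransientError(TTMError):
    """Repolarization / decay never reached the requested level inside the window."""


class DegenerateBaselineError(TTMError):
    """A baseline-phase kinetic parameter is <= 0, so the post/baseline ratio is undefined."""


class EmptyAggregateError(TTMError):
    """All records entering an aggregation step were unusable."""


class DegenerateVehicleError(TTMError):
    """Vehicle measurements have zero spread; Gaussian scoring is impossible."""


class MissingVehicleError(TTMError):
    """No vehicle (concentration 0) rows were found in a parameter table."""


class ShapeInfeasibleError(TTMError):
    """Requested synthetic waveform targets cannot be realised by the template."""


class SchemaError(TTMError):
    """A tabular file is missing required columns."""
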