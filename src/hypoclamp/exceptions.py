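"""Exception hierarchy for hypoclamp."""


class HypoclampError(Exception):
    """Base class for all package errors."""


class UnitError(HypoclampError):
    """Unknown unit string or unsupported conversion pair."""


class ValidationError(HypoclampError):
    """A record, series or cohort violates its contract."""


class ProtocolError(HypoclampError):
    """Protocol configuration violates its invariants."""


class AlignmentError(HypoclampError):
    """Hypoglycaemic-window alignment is impossible for a record."""


class SimulationError(HypoclampError):
    """The virtual-subject ODE integration failed or produced
    a physiologically impossible state."""


class EstimationError(HypoclampError):
    """A flux or secretion estimator received inadmissible input."""


class IdentifiabilityError(EstimationError):
    """A model fit has no unique solution on the given data."""
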