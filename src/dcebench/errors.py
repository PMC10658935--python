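"""Exception hierarchy shared by all pipeline stages."""


class DceBenchError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(DceBenchError):
    """Acquisition protocol violates the DCE-MRI conventions (e.g. <3 timepoints)."""


class GeometryError(DceBenchError):
    """Requested geometry does not fit the volume, or a VOI is out of bounds."""


class IntegrityError(DceBenchError):
    """Shapes, spacings or recorded dimensions disagree between paired inputs."""


class DegenerateDataError(DceBenchError):
    """Input carries no usable structure (e.g. all feature vectors identical)."""


class ConfigurationError(DceBenchError):
    """A run configuration is internally inconsistent or incomplete."""


class StateError(DceBenchError):
    """An operation was invoked on an object in the wrong state (e.g. untrained model)."""


class DegenerateTestError(DceBenchError):
    """A statistical test cannot be formed (e.g. all paired differences are zero)."""


class EmptySummaryError(DceBenchError):
    """No defined values are available to summarize."""


class DependencyError(DceBenchError):
    """An experiment stage requires an output that no planned stage produces."""
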