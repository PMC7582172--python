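"""Exception hierarchy shared across the pipeline."""


class ProtoconnError(Exception):
    """Base class for all package errors."""


class ValidationError(ProtoconnError):
    """An input violates a documented precondition."""


class GeometryError(ProtoconnError):
    """A voxel structure does not fit the grid it was declared on."""


class FormatError(ProtoconnError):
    """An on-disk table or volume has the wrong shape/columns."""


class PipelineError(ProtoconnError):
    """A stage cannot proceed (e.g. every parcel was emptied by exclusion)."""


class MatchingError(ProtoconnError):
    """Cohort matching is infeasible (e.g. not enough same-sex controls)."""
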