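"""Exception types used across the toolkit."""


class GcrToolsError(Exception):
    """Base class for all toolkit errors."""


class SpecificationError(GcrToolsError):
    """A simulation or analysis was configured with invalid parameters."""


class DataError(GcrToolsError):
    """Input data violates a precondition (mismatched grids, bad values...)."""


class CapacityError(GcrToolsError):
    """Requested placement does not fit in the genome."""


class UndefinedRatioError(GcrToolsError):
    """A coverage ratio with zero denominator coverage."""
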