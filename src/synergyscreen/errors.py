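"""Exception hierarchy shared across the pipeline stages."""


class SynergyScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(SynergyScreenError):
    """A table's header does not match its declared schema."""


class ValidationError(SynergyScreenError):
    """Row-level content violates a contract (bad value, duplicate key...)."""


class DegenerateControlError(SynergyScreenError):
    """Vehicle-control wells are missing or average to zero signal."""


class InsufficientDataError(SynergyScreenError):
    """Too few usable points for the requested fit or test."""


class InvalidFitError(SynergyScreenError):
    """A median-effect fit produced non-physical parameters (m <= 0)."""


class DegenerateTestError(SynergyScreenError):
    """A statistical test is undefined on this input (e.g. zero events)."""
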