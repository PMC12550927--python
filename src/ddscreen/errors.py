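"""Exception hierarchy for the ddscreen pipeline.

Every stage raises a named error so the CLI can map failures to distinct
exit codes and callers can react to specific conditions (a saturated well,
a QC-excluded well, a malformed input file) without string matching.
"""


class DdscreenError(Exception):
    """Base class for all ddscreen errors."""


class ConfigError(DdscreenError):
    """Invalid assay configuration, cutoffs, or pipeline config file."""


class SaturationError(DdscreenError):
    """All droplets positive (or expected load beyond the dynamic range):
    the Poisson concentration is undefined."""


class InsufficientDataError(DdscreenError):
    """Too few droplets or replicates for the requested computation."""


class ExcludedWellError(DdscreenError):
    """Operation on a well that failed accepted-event QC without override."""


class NoReferenceError(DdscreenError):
    """Copy-number requested with zero reference-gene concentration."""


class UnqualifiedSampleError(DdscreenError):
    """SMN classification requested for an unqualified sample."""


class SecondTierPreconditionError(DdscreenError):
    """Second-tier interpretation called on a non-presumptive sample."""


class SchemaError(DdscreenError):
    """Input table missing a required column or holding non-numeric data."""


class EmptyInputError(DdscreenError):
    """Input file contains no rows."""
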