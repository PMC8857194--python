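"""Exception hierarchy.

All herbnet errors derive from :class:`HerbnetError` so callers can catch
the whole family; the concrete classes distinguish schema problems in input
files, referential-integrity violations, bad or missing data values,
infeasible null-model sampling, and the undefined single-compound gene
weight under the strict denominator policy.
"""


class HerbnetError(Exception):
    """Base class for all herbnet errors."""


class SchemaError(HerbnetError):
    """An input file does not conform to the documented column schema."""


class IntegrityError(HerbnetError):
    """A record references an identifier that does not exist."""


class DataError(HerbnetError):
    """A required value is missing or out of range (e.g. no OB/DL, no score)."""


class SamplingError(HerbnetError):
    """A bin does not contain enough herbs to draw the requested sample."""


class UndefinedWeightError(DataError):
    """Gene weight denominator ln(1) = 0 under the strict policy."""


class ParameterError(HerbnetError, ValueError):
    """Generator or configuration parameters are infeasible."""
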