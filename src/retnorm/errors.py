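"""Exception hierarchy shared across the package.

Three broad families map onto the CLI exit codes: configuration problems
(:class:`ParameterError`), input/output problems (plain ``OSError`` from the
standard library plus :class:`IntegrityError`), and data problems (everything
deriving from :class:`DataError`).
"""


class RetnormError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RetnormError, ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class DimensionError(RetnormError, ValueError):
    """An array input does not have the contracted shape."""


class DataError(RetnormError):
    """A computation cannot proceed because of the data it was given."""


class MissingCellError(DataError, KeyError):
    """A normative-database lookup did not match any cell."""

    def __init__(self, group, eye, age_months, layer, region):
        self.key = (group, eye, age_months, layer, region)
        super().__init__(
            f"no normative cell for group={group!r}, eye={eye!r}, "
            f"age_months={age_months!r}, layer={layer!r}, region={region!r}"
        )


class NoDataError(DataError):
    """Too few valid values remain to compute the requested summary."""


class InsufficientDataError(DataError):
    """A statistical routine received fewer observations than it requires."""


class DegenerateDistributionError(DataError):
    """A reference or sample distribution has zero spread where spread is required."""


class IntegrityError(RetnormError):
    """A packaged data file does not match its recorded checksum."""
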