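"""Exception hierarchy for plantshift.

Every error raised on bad input derives from :class:`PlantShiftError` so
callers can catch the package's failures with a single ``except``.
"""


class PlantShiftError(Exception):
    """Base class for all plantshift errors."""


class SchemaError(PlantShiftError):
    """An input file is missing required columns or keys."""


class ValidationError(PlantShiftError):
    """A record violates a domain invariant (names the offending record)."""


class ReferentialError(PlantShiftError):
    """A foreign key (item id, participant id) cannot be resolved."""


class UnresolvedItemError(PlantShiftError):
    """Items lack an amino-acid profile and no donor mapping covers them."""

    def __init__(self, item_ids):
        self.item_ids = sorted(item_ids)
        super().__init__(
            "items without amino-acid profile and no donor mapping: "
            + ", ".join(self.item_ids)
        )


class CoverageError(PlantShiftError):
    """A non-conforming food group has no replacement alternatives."""


class CalibrationError(PlantShiftError):
    """Synthetic-data targets are infeasible for the configured menu."""


class DomainError(PlantShiftError):
    """A numeric argument is outside its mathematical domain."""


class CompletenessError(PlantShiftError):
    """A report is missing required strata."""


class EmptyInputError(PlantShiftError):
    """An operation that needs data received an empty dataset."""
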