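"""Exception hierarchy for roster validation and model fitting."""


class DVIPriorError(Exception):
    """Base class for all package errors."""


class RosterSchemaError(DVIPriorError):
    """A required column is missing from a roster file."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"roster file is missing required column {column!r}")


class RosterIntegrityError(DVIPriorError):
    """Duplicate victim identifiers or other cross-record inconsistencies."""


class RosterParseError(DVIPriorError):
    """A row of a roster file could not be parsed (carries the row number)."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ProfileError(DVIPriorError):
    """A candidate filter references a category label absent from the roster."""


class PartitionError(DVIPriorError):
    """A record cannot be placed in any cell of the requested partition."""


class ElicitationError(DVIPriorError):
    """The coefficient-of-variation constraint admits no valid prior.

    Raised when the most populated cell holds at least half of all
    candidates, which drives the Dirichlet concentration alpha0 = N/N_k - 2
    to zero or below.
    """

    def __init__(self, n_total: int, n_max: int, cv_target: float = 1.0):
        self.n_total = n_total
        self.n_max = n_max
        self.cv_target = cv_target
        super().__init__(
            f"CV={cv_target} constraint infeasible: most populated cell has "
            f"N_k={n_max} of N={n_total} candidates (alpha0 would be <= 0)"
        )


class SplitError(DVIPriorError):
    """A cross-validation split cannot produce non-empty learning and
    reserved samples."""


class ConfigError(DVIPriorError):
    """Invalid synthetic-cohort or run configuration."""
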