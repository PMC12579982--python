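"""Exception hierarchy for capsbench."""


class CapsBenchError(Exception):
    """Base class for all capsbench errors."""


class SchemaError(CapsBenchError):
    """An input table is missing a required column or has a bad layout."""


class RowValidationError(CapsBenchError):
    """A row violates a record-level invariant; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ContextError(CapsBenchError):
    """A trinucleotide context cannot be assigned (e.g. contains N)."""


class MissingContextError(CapsBenchError):
    """A query group contains context classes absent from the reference model."""

    def __init__(self, contexts, where: str = "reference model"):
        self.contexts = sorted(str(c) for c in contexts)
        super().__init__(
            f"{len(self.contexts)} context class(es) absent from {where}: "
            + ", ".join(self.contexts[:10])
            + ("..." if len(self.contexts) > 10 else "")
        )


class EmptyGroupError(CapsBenchError):
    """A variant group is empty; the statistic is undefined."""


class ModelConstructionError(CapsBenchError):
    """A reference model could not be built (e.g. empty reference set)."""


class DegenerateFitError(CapsBenchError):
    """The mutability regression is rank-deficient (constant mutability)."""


class ConfigurationError(CapsBenchError):
    """Inconsistent tool registry / filter specification."""


class UnsupportedPredicateError(CapsBenchError):
    """A group predicate depends on realized noise, so no closed form exists."""
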