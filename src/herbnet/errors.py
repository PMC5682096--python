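"""Structured exceptions shared across the pipeline."""


class HerbnetError(Exception):
    """Base class for all package errors."""


class ValidationError(HerbnetError):
    """Input data or parameters violate a documented contract."""


class DimensionMismatchError(ValidationError):
    """Descriptor vectors of unequal length were combined."""


class UndefinedSimilarityError(ValidationError):
    """Tanimoto similarity requested for two all-zero vectors."""


class LoaderError(ValidationError):
    """A file did not conform to its expected dialect.

    Carries file/line context so malformed rows are reported precisely.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line
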