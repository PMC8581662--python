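"""Exception hierarchy shared across the pipeline stages."""


class MethmarkError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MethmarkError, ValueError):
    """An invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(MethmarkError, ValueError):
    """A malformed input table (bad header, bad row, wrong dtype)."""


class OrderingError(SchemaError):
    """A manifest that is not sorted by (chromosome, position)."""


class InputError(MethmarkError, ValueError):
    """Invalid data passed to a statistical kernel."""


class CoverageError(MethmarkError, ValueError):
    """A region with no member sites present in the data."""


class StratumError(MethmarkError, ValueError):
    """An empty or undersized sample stratum."""


class InsufficientEvidenceError(MethmarkError, ValueError):
    """No informative counts to estimate a rate from."""


class RegistryError(MethmarkError, ValueError):
    """Classifier registry misuse (e.g. duplicate name)."""
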