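"""Exception types shared across the package."""


class KelpTpcError(Exception):
    """Base class for all package errors."""


class InvalidInputError(KelpTpcError, ValueError):
    """A scalar input violates a precondition (e.g. non-positive elapsed days)."""


class SchemaError(KelpTpcError, ValueError):
    """Tabular input fails validation; message lists offending row numbers."""


class ConfigurationError(KelpTpcError, ValueError):
    """Required configuration is missing or inconsistent (e.g. no blanks for a treatment)."""


class RegistryError(KelpTpcError, KeyError):
    """Unknown model name requested from the TPC model registry."""


class DegenerateDataError(KelpTpcError, ValueError):
    """Dataset cannot support the requested operation (e.g. all-zero rates)."""


class SelectionError(KelpTpcError, RuntimeError):
    """Model selection cannot proceed (e.g. empty admissible set)."""


class InfeasibleInputError(KelpTpcError, ValueError):
    """Carbonate-system inputs admit no physical solution."""
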