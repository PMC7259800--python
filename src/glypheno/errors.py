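"""Exception hierarchy shared across the package."""


class GlyphenoError(Exception):
    """Base class for all package errors."""


class SchemaError(GlyphenoError):
    """A table is missing required columns or has an unreadable layout."""


class ValidationError(GlyphenoError):
    """A value violates its legal set (domain score, ΔΔG, position, ...)."""


class ContractError(GlyphenoError):
    """An operation was called with inputs violating its contract."""


class ConfigError(GlyphenoError):
    """A pipeline configuration is inconsistent (e.g. predict before train)."""
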