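"""Exception hierarchy shared across the package."""


class NeuromotifError(Exception):
    """Base class for package errors."""


class ValidationError(NeuromotifError, ValueError):
    """Input failed a contract check (shape, range, missing field, ...)."""


class CatalogueError(NeuromotifError, KeyError):
    """Unknown motif identifier."""
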