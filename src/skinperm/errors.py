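"""Exception hierarchy shared across the pipeline."""


class SkinpermError(Exception):
    """Base class for all skinperm errors."""


class SchemaError(SkinpermError):
    """A tabular input is missing a required column or key."""


class ValidationError(SkinpermError):
    """A value violates a physical or structural invariant."""


class InsufficientDataError(SkinpermError):
    """Too few observations to perform a fit or a test."""
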