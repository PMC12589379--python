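"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI lives in :mod:`petref.cli`; library code only
raises these types.
"""


class PetrefError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PetrefError):
    """Inputs violate a documented precondition or invariant."""


class FormatError(PetrefError):
    """A file could be read but does not match the expected structure."""


class ExtractionError(PetrefError):
    """IDIF extraction failed (no carotid component / empty mask)."""


class StageError(PetrefError):
    """A pipeline stage failed; message is stage-attributed."""
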