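"""Typed exceptions raised across the package.

Every malformed input raises one of these; nothing falls back to a silent
default.
"""


class CytoplexError(Exception):
    """Base class for all package errors."""


class SchemaError(CytoplexError):
    """A required column, marker or definition is missing or inconsistent."""


class ValidationError(CytoplexError):
    """Input values violate a documented invariant (negative intensity, ...)."""


class MaskError(CytoplexError):
    """Compartment masks are malformed (shape mismatch, bad scale, ...)."""


class ConfigError(CytoplexError):
    """Run configuration is out of range or names an unsupported method."""


class CutoffError(CytoplexError):
    """Cutoff optimisation could not select any admissible cutoff."""
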