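"""Error types shared across the package."""


class DbpredError(Exception):
    """Base class for all library errors."""


class FormatError(DbpredError):
    """A file is syntactically malformed (not parseable in its declared format)."""


class ValidationError(DbpredError):
    """Parsed data violates a domain invariant (alphabet, shapes, labels, ids)."""


class LengthError(ValidationError):
    """A sequence or profile is too short for the requested descriptor."""
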