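"""Package-wide exception types."""


class FlavokinError(ValueError):
    """Base class for all flavokin validation errors."""


class InvalidMechanismError(FlavokinError):
    """A kinetic mechanism violates its invariants (e.g. non-positive rate)."""


class InvalidInputError(FlavokinError):
    """Input data violate a precondition (shape, ordering, sign, coverage)."""


class ParseError(FlavokinError):
    """A file could not be parsed into a valid domain object."""
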