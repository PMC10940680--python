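"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A user-supplied parameter is outside its admissible range."""


class InvalidInputError(ValueError):
    """Input data violate a structural precondition (shapes, ids, labels)."""


class NumericalConditioningError(RuntimeError):
    """A matrix factorization failed; usually fixable with a larger ridge."""
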