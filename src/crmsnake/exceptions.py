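"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A configuration or algorithm parameter violates its contract."""


class InvalidInputError(ValueError):
    """An input image, contour, or field violates its contract."""


class NumericalDivergenceError(ArithmeticError):
    """An iterative scheme left its stability region and diverged."""
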