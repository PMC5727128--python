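"""Exception hierarchy shared across the package."""


class PhyloAllometryError(Exception):
    """Base class for all package errors."""


class ValidationError(PhyloAllometryError, ValueError):
    """Invalid inputs: mismatched tip sets, non-positive traits, bad levels."""


class TreeParseError(PhyloAllometryError, ValueError):
    """A tree file could not be parsed in the requested dialect."""


class NumericalError(PhyloAllometryError, ArithmeticError):
    """A linear-algebra step failed (e.g. singular phylogenetic covariance)."""
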