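"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`OepError`
so callers (and the CLI) can distinguish validation problems from bugs.
"""


class OepError(Exception):
    """Base class for all errors raised by oeptools."""


class ValidationError(OepError, ValueError):
    """An input violates a documented invariant or precondition."""


class UnknownDrugError(OepError, KeyError):
    """A drug name was not found in the formulary."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return f"unknown drug in formulary: {self.name!r}"


class FormularyParseError(OepError, ValueError):
    """A formulary file failed schema validation."""


class InfeasibleRegimenError(OepError):
    """No tablet combination achieves the prescribed dose within tolerance.

    Carries the nearest achievable daily totals so the prescriber can decide
    whether to relax the tolerance or change the target dose.
    """

    def __init__(self, message: str, nearest: tuple[float, ...] = ()):
        super().__init__(message)
        self.nearest = nearest
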