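"""Exception hierarchy shared across the package."""


class CupFAError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CupFAError, ValueError):
    """An input angle or record lies outside its validation window.

    The message names the offending field so CLI callers can report it.
    """


class ContractError(CupFAError):
    """An internal pre-condition was violated (e.g. a non-unit direction vector)."""


class DegenerateOrientationError(CupFAError):
    """The cup normal points medially or vertically: its axial projection has a
    non-positive lateral component, so transverse-plane anteversion is undefined
    in the lateral-opening convention."""


class SingularDesignError(CupFAError):
    """The regression design matrix is rank deficient, typically because one of
    the predictor variables is (nearly) constant across the samples."""


class TableParseError(CupFAError, ValueError):
    """A study table file is malformed; the message carries the row number."""


class ScenarioConstructionError(CupFAError):
    """A requested classification pattern cannot be realised by any spinopelvic
    profile under the given tolerance band."""
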