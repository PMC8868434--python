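"""Exception hierarchy shared across lipidqi modules."""


class LipidqiError(Exception):
    """Base class for all package-specific errors."""


class ShorthandParseError(LipidqiError, ValueError):
    """A fatty-acid shorthand code does not match the expected grammar.

    Attributes
    ----------
    code : str
        The offending code as given.
    token : str
        The token (or description of the token) that failed.
    """

    def __init__(self, code: str, token: str, message: str):
        self.code = code
        self.token = token
        super().__init__(f"cannot parse {code!r}: {message} (offending token: {token!r})")


class UnsupportedPolyeneClassError(LipidqiError, ValueError):
    """Double-bond count outside the monoenoic..hexaenoic range supported
    by the unsaturation-index weighting."""


class ProfileLoadError(LipidqiError, ValueError):
    """A profile CSV could not be loaded; carries the 1-based row number
    when the problem is tied to a specific row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DuplicateCodeError(ProfileLoadError):
    """The same canonical shorthand code appears twice in one profile."""


class UndefinedIndexError(LipidqiError, ZeroDivisionError):
    """An index denominator is zero for the given group sums."""

    def __init__(self, index: str, reason: str):
        self.index = index
        super().__init__(f"index {index!r} is undefined: {reason}")


class AssayValueError(LipidqiError, ValueError):
    """Invalid absorbance or dose-response input."""


class UnitMismatchError(AssayValueError):
    """Concentration units differ within one dose-response series."""


class NoEstimateError(LipidqiError, RuntimeError):
    """IC50 cannot be estimated from the given series; message carries a
    diagnostic of what was tried."""


class ConfigError(LipidqiError, ValueError):
    """Invalid CLI/YAML run configuration."""
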