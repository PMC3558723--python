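"""Exception types shared across the package."""


class TcrSurveyError(Exception):
    """Base class for all package errors."""


class NoCrystalContextError(TcrSurveyError):
    """The file carries no usable unit cell / symmetry information.

    Sequence-level operations (sequon scanning, manifest checks) may still
    proceed on such a structure; lattice operations cannot.
    """


class UnknownSpaceGroupError(TcrSurveyError):
    """The Hermann-Mauguin symbol could not be resolved to operators."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown space group symbol: {symbol!r}")


class ManifestError(TcrSurveyError):
    """The annotation manifest is inconsistent with itself or a structure."""


class ConfigError(TcrSurveyError):
    """A survey configuration file contains an unknown or malformed key."""


class InsufficientCoordinatesError(TcrSurveyError):
    """Too few resolved residues to assess a candidate pair."""
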