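"""Exception hierarchy for the package."""


class RayleighSimError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(RayleighSimError, ValueError):
    """Two spectral objects do not share the same wavelength grid."""


class SpectralIOError(RayleighSimError, ValueError):
    """Malformed spectral CSV input; the message names the offending row."""


class ShiftOutOfRangeError(RayleighSimError, ValueError):
    """A frequency shift would move the pigment's support off the grid."""


class NoMatchInRangeError(RayleighSimError):
    """The excitation-ratio curve never crosses the amber ratio on the scale.

    Carries the sign of the log-ratio mismatch at both scale ends, which
    diagnoses beyond which end of the instrument range the match lies.
    This is the mechanism behind the 'extreme anomalous' exclusion: such
    observers' matching behaviour reaches an end of the scale.
    """

    def __init__(self, message: str, f_low: float, f_high: float):
        super().__init__(message)
        self.f_low = f_low
        self.f_high = f_high


class MatchIndeterminateError(RayleighSimError):
    """The mixture and amber excitation ratios coincide at every setting.

    Happens when the observer's two cones are identical (e.g. an anomalous
    observer constructed with a zero pigment shift): such an observer accepts
    the entire scale as a match, so no unique setting exists.
    """


class UnreachableTargetError(RayleighSimError):
    """No pigment shift inside the search bounds can produce the target match."""
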