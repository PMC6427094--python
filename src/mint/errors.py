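"""Exception hierarchy for the MINT toolkit.

Every error raised by the package derives from :class:`MintError` so callers
can catch toolkit failures without masking programming errors.
"""


class MintError(Exception):
    """Base class for all MINT toolkit errors."""


class ConstraintError(MintError):
    """Melody-generation constraints are infeasible; message names the bound."""


class UnscramblableMelodyError(MintError):
    """No distinct-order permutation of the melody's notes exists."""


class PitchRangeError(MintError):
    """A pitch falls outside the configured MIDI range."""


class EmptyInputError(MintError):
    """An operation received an empty melody or signal."""


class DegenerateSignalError(MintError):
    """A signal is identically zero where nonzero content is required."""


class RampTooLongError(MintError):
    """Requested amplitude ramp exceeds half the waveform duration."""


class UndefinedSNRError(MintError):
    """SNR is undefined because the masker has zero energy in the window."""


class CoverageError(MintError):
    """Masker streams cannot cover the required pitch range."""


class BedTooShortError(MintError):
    """Masker bed is shorter than the melody plus excerpt margin."""


class GeometryError(MintError):
    """Target does not fit inside the masker excerpt at the embed offset."""


class ManifestError(MintError):
    """A response references a trial id absent from the session manifest."""


class InputError(MintError):
    """Malformed scoring input (duplicate responses, mismatched subjects...)."""


class PoolError(MintError):
    """Stimulus pool too small to fill a session block."""
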