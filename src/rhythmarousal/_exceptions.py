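"""Exception hierarchy shared across the package."""


class RhythmArousalError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RhythmArousalError, ValueError):
    """Invalid configuration (bad transition matrix, negative rate, ...)."""


class ParameterError(RhythmArousalError, ValueError):
    """Analysis parameter outside its valid range (e.g. cutoff >= Nyquist)."""


class DataError(RhythmArousalError, ValueError):
    """Malformed input data (non-finite samples, length mismatch, ...)."""


class AlignmentError(RhythmArousalError, ValueError):
    """Clock alignment impossible (too few TTL pulses, unmatched trains)."""


class ProtocolError(RhythmArousalError, ValueError):
    """Patch-clamp protocol violation (overlapping steps, short baseline)."""


class TrialRejectedError(RhythmArousalError, ValueError):
    """A trial failed its precondition (e.g. animal awake at stimulus onset)."""
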