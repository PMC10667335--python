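"""Exception hierarchy for the pdvoice pipeline."""


class PdVoiceError(Exception):
    """Base class for all pdvoice errors."""


class FormatError(PdVoiceError):
    """A file is not mono 16-bit RIFF PCM, or is truncated/empty."""


class DegenerateSignalError(PdVoiceError):
    """A signal is all-zero or otherwise carries no usable energy."""


class UnvoicedRecordingError(PdVoiceError):
    """No voiced frames were found; pitch-based features are undefined."""


class TooFewCyclesError(PdVoiceError):
    """Not enough glottal cycles for the requested perturbation measure."""


class ConditioningError(PdVoiceError):
    """An autocorrelation sequence is not positive definite (|c_k| >= 1)."""


class ProtocolError(PdVoiceError):
    """An evaluation split or model input violates the protocol contract."""
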