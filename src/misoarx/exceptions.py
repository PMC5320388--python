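"""Exception hierarchy for the misoarx package."""


class MisoarxError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MisoarxError, ValueError):
    """Signals have incompatible lengths or sampling rates."""


class EmptyDecompositionError(MisoarxError, ValueError):
    """No peak in the template qualifies as a component."""


class DegenerateWindowError(MisoarxError, ValueError):
    """A component window would have zero width."""


class UnderdeterminedError(MisoarxError, ValueError):
    """Fewer regression rows than free parameters."""


class AllUndetectedError(MisoarxError, ValueError):
    """Sparse coding selected no atom for any component."""


class UndefinedLatencyError(MisoarxError, ValueError):
    """A component waveform is flat inside the latency search window."""


class FormatError(MisoarxError, ValueError):
    """A trials/waveform file is malformed; the message names the line."""
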