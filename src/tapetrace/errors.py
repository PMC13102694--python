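"""Exception types raised across the readout stack."""


class TapetraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(TapetraceError, ValueError):
    """A growth/waveform/schedule model violates its invariants."""


class ConfigurationError(TapetraceError, ValueError):
    """Inconsistent run configuration (channel collisions, unknown names...)."""


class InfeasibleGeometryError(TapetraceError, ValueError):
    """Requested fiber geometry cannot be confined at the given curvature."""


class OutOfBoundsError(TapetraceError, ValueError):
    """A fiber or sample point leaves the rendered volume."""


class UndefinedGeometryError(TapetraceError, ValueError):
    """Too few / degenerate points for a geometric statistic."""


class UndefinedCorrelationError(TapetraceError, ValueError):
    """Pearson correlation undefined (zero-variance reference)."""


class DivisionUnsafeError(TapetraceError, ValueError):
    """Baseline too small for relative-change normalization."""

    def __init__(self, channel: str, baseline: float):
        self.channel = channel
        self.baseline = baseline
        super().__init__(
            f"baseline for channel {channel!r} is {baseline:.3g}; "
            "relative change undefined"
        )


class DetectionFailure(TapetraceError, RuntimeError):
    """A timestamp event could not be located on the profile."""


class InvalidAnchorsError(TapetraceError, ValueError):
    """Timestamp anchors are not strictly increasing in fraction and time."""


class InconsistencyError(TapetraceError, KeyError):
    """Cross-referenced artifacts disagree (e.g. label without a skeleton)."""
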