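"""Exception hierarchy.

Every error raised by the package derives from :class:`VibemgError`, so callers
(and the batch pipeline, which records per-trial failures and keeps going) can
catch one base class.
"""


class VibemgError(Exception):
    """Base class for all vibemg errors."""


class TrialFormatError(VibemgError):
    """A trial file does not follow the documented CSV layout."""


class TrialDataError(VibemgError):
    """A trial file parses but its contents are invalid (NaN, non-monotonic time, ...)."""


class ManifestError(VibemgError):
    """A session manifest is malformed (duplicate labels, missing pre, ...)."""


class ParameterError(VibemgError, ValueError):
    """An analysis parameter is out of range for the data (e.g. band edge >= Nyquist)."""


class OnsetError(VibemgError):
    """Movement onset could not be located in the joint-angle signal."""


class ThresholdError(VibemgError):
    """The activation threshold could not be estimated (no pre-onset segment)."""


class SegmentationError(VibemgError):
    """Flexion-extension cycles could not be detected or selected."""


class MetricError(VibemgError):
    """A summary metric is undefined for the given inputs."""


class RatioError(VibemgError):
    """A post/pre ratio is undefined (zero or missing baseline RMS)."""


class StatsError(VibemgError):
    """A statistical model or test could not be computed."""
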