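"""Exception hierarchy.

Every error raised on a user-facing contract violation derives from
:class:`SummdivError`, so the CLI can map any domain failure to exit code 1.
"""


class SummdivError(Exception):
    """Base class for all domain errors."""


class ValidationError(SummdivError):
    """A record or table violates a structural invariant."""


class CorpusParseError(SummdivError):
    """A corpus or ratings file could not be parsed; names the record/line."""


class PairingError(SummdivError):
    """A corpus is not paired-complete for a requested system comparison."""


class DegenerateGeometryError(SummdivError):
    """Embedding geometry is degenerate (zero-norm vector or zero centroid)."""


class UndefinedEffectError(SummdivError):
    """Cohen d is undefined because the pooled variance is zero."""
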