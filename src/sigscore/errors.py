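"""Exception types raised across the package."""


class SigscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(SigscoreError, ValueError):
    """Input violates a documented contract (shapes, ranges, permutations...)."""


class ParseError(SigscoreError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ScoringRefusedError(SigscoreError):
    """Too few signature genes survive mapping for a meaningful t-score."""


class PipelineError(SigscoreError):
    """A pipeline stage failed; the message names the stage."""
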