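"""Exception hierarchy for the csfdyn pipeline.

All data-level failures derive from :class:`CsfDynError` so the CLI can map
them to a non-zero exit status distinct from usage errors.
"""


class CsfDynError(Exception):
    """Base class for pipeline errors."""


class ProtocolError(CsfDynError):
    """A required protocol event (e.g. ``infusion_start``) is missing or malformed."""


class UnstableBaselineError(CsfDynError):
    """No sufficiently long steady pre-infusion span could be found."""


class InsufficientDataError(CsfDynError):
    """A segment is too short (or has too few valid points) for the requested statistic."""


class FitFailedError(CsfDynError):
    """Model fit did not converge; carries the best incumbent parameters."""

    def __init__(self, message, incumbent=None):
        super().__init__(message)
        self.incumbent = incumbent


class SeparationWarning(UserWarning):
    """Logistic fit encountered (quasi-)complete separation."""


class ParseError(CsfDynError):
    """A CSV input violated the declared schema; message names the line."""
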