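"""Exception hierarchy for the sedentary-pattern pipeline.

Readers and model fits reject malformed input rather than repairing it;
every error message identifies the offending row, column, or participant.
"""


class SedpatternsError(Exception):
    """Base class for all package errors."""


class ConfigError(SedpatternsError):
    """Invalid configuration (bad distribution parameters, impossible schedules)."""


class FormatError(SedpatternsError):
    """A file does not match the documented CSV dialect (missing/unknown columns)."""


class IntegrityError(SedpatternsError):
    """Structurally valid file with impossible content (timestamp gaps, negative counts)."""


class ValidationError(SedpatternsError):
    """A record violates a domain invariant (score out of range, wake before bed)."""


class LinkageError(SedpatternsError):
    """Cross-file participant identifiers do not resolve."""


class InsufficientDataError(SedpatternsError):
    """Too few complete cases to fit the requested model."""


class CollinearityError(SedpatternsError):
    """Rank-deficient design matrix; names the collinear columns."""


class PipelineError(SedpatternsError):
    """A pipeline stage failed; carries stage name and participant context."""

    def __init__(self, stage: str, message: str, participant_id: str | None = None):
        self.stage = stage
        self.participant_id = participant_id
        ctx = f" [participant={participant_id}]" if participant_id else ""
        super().__init__(f"stage '{stage}'{ctx}: {message}")
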