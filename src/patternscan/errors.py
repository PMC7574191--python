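"""Exception hierarchy for patternscan."""


class PatternScanError(Exception):
    """Base class for all patternscan errors."""


class InvalidRegion(PatternScanError):
    """A region violates basic interval invariants (e.g. end <= start)."""


class MissingMate(PatternScanError):
    """A loop-track region has no paired mate region."""


class ParseError(PatternScanError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class ConfigError(PatternScanError):
    """A pattern configuration file names an invalid field or value."""


class UnresolvedTarget(ConfigError):
    """A pattern track's target_track_name matches no loaded track."""


class NoGenesFound(PatternScanError):
    """No gene/transcript feature could be extracted from a gene model."""


class LengthMismatch(PatternScanError):
    """Query and target center lists differ in length."""


class NoPerfectTrack(PatternScanError):
    """A pattern has no perfect-matching track to anchor the search on."""


class InstanceTooLarge(PatternScanError):
    """The exhaustive oracle would enumerate too many assignments."""


class EmptyUniverse(PatternScanError):
    """The background gene universe for enrichment is empty."""


class GenomeTooSmall(PatternScanError):
    """The toy genome cannot accommodate the requested planted occurrences."""
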