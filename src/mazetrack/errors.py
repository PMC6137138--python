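"""Exception hierarchy shared across the toolbox."""


class MazetrackError(Exception):
    """Base class for all toolbox errors."""


class FormatError(MazetrackError):
    """Input file exists but cannot be decoded as a supported video/stack."""


class ConfigError(MazetrackError):
    """Missing or inconsistent configuration (preferences) values."""


class ConvergenceError(MazetrackError):
    """The auto-threshold histogram never became bimodal."""


class EmptyTrackError(MazetrackError):
    """No frame of the video yielded a detection; no trajectory exists."""


class StageError(MazetrackError):
    """Pipeline failure wrapper carrying the name of the failing stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
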