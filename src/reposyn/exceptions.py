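"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: InputError (and subclasses) -> 2,
StageError -> 3.
"""


class ReposynError(Exception):
    """Base class for all package errors."""


class ConfigError(ReposynError, ValueError):
    """Invalid configuration (bad counts, inconsistent thresholds, unknown keys)."""


class InputError(ReposynError, ValueError):
    """Invalid input data (bad doses, missing groups, malformed tables)."""


class ParseError(InputError):
    """Malformed file; message names the offending line where possible."""


class FitError(ReposynError, RuntimeError):
    """A model fit could not be performed (too few usable points, degenerate data)."""


class StageError(ReposynError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
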