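"""Exception hierarchy shared across the pipeline.

The command-line front end maps these onto exit codes: usage errors exit 1,
validation/configuration errors exit 2, stage failures exit 3.
"""


class SaltnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SaltnetError, ValueError):
    """A configuration value is out of range or inconsistent."""


class ValidationError(SaltnetError, ValueError):
    """Input data violates a contract (shape, range, duplicate symbols...)."""


class StageError(SaltnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
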