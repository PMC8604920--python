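"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes: configuration problems (bad
specs, unparseable patterns, missing files) exit 2, data problems (empty
cohorts, inconsistent records) exit 3, anything else exits 1.
"""


class WpnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WpnetError):
    """Invalid user-supplied configuration (spec fields, pattern syntax, paths)."""


class PatternSyntaxError(ConfigurationError):
    """An ICD code pattern could not be parsed."""

    def __init__(self, raw: str, reason: str = "") -> None:
        msg = f"unparseable ICD pattern {raw!r}"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)
        self.raw = raw


class DataError(WpnetError):
    """Structurally invalid or unusable input data."""


class DataIntegrityError(DataError):
    """A patient's rows contradict each other (e.g. varying age or gender)."""


class EmptyCohortError(DataError):
    """Filtering removed every patient; the cohort is empty."""


class TrainingError(WpnetError):
    """Optimisation diverged (non-finite loss or activations)."""
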