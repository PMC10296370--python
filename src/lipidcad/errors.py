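"""Exception hierarchy.

Configuration problems and data problems are distinct because the command
line maps them to different exit codes (2 and 3 respectively).
"""


class LipidcadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipidcadError):
    """Invalid configuration value (bad probability, negative SD, ...)."""


class DataError(LipidcadError):
    """Malformed or inconsistent input data."""


class AlignmentError(DataError):
    """Clinical table and lipid matrix do not describe the same samples."""


class AnalysisError(LipidcadError):
    """A statistical stage cannot proceed (empty control set, singular
    system, non-convergence, ...)."""
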