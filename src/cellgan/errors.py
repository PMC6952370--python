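"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are handled by click (2),
:class:`ParameterError`/:class:`DegenerateOutputError` map to 3 (validation),
:class:`FormatError`/:class:`IntegrityError`/:class:`AlignmentError` map to 4
(data integrity).
"""


class CellGanError(Exception):
    """Base class for all package errors."""


class FormatError(CellGanError):
    """A file does not look like the expected on-disk format."""


class IntegrityError(CellGanError):
    """Internally inconsistent data (dimension mismatches, leakage, ...)."""


class AlignmentError(CellGanError):
    """Gene/cell identifier sets of two objects cannot be aligned."""


class ParameterError(CellGanError):
    """An argument is outside its valid domain."""


class DegenerateOutputError(CellGanError):
    """An operation would return an empty or otherwise unusable result."""


class TrainingDivergedError(CellGanError):
    """Loss became non-finite during adversarial training."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
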