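"""Exception hierarchy for vgscan."""


class VgscanError(Exception):
    """Base class for all package errors."""


class PDBParseError(VgscanError):
    """A PDB record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TopologyError(VgscanError):
    """Models of an ensemble disagree on atom count or identity."""


class FormatOverflowError(VgscanError):
    """A value does not fit the fixed columns of the output format."""


class ParameterError(VgscanError):
    """A required per-atom or per-residue parameter is missing."""


class FragmentationError(VgscanError):
    """Truncation produced an empty or chemically inconsistent fragment."""


class MutationError(VgscanError):
    """A residue cannot be mutated (missing atoms, unsupported type)."""


class EngineError(VgscanError):
    """An external energy engine failed to run."""

    def __init__(self, message: str, log: str = ""):
        self.log = log
        super().__init__(message)


class EngineParseError(VgscanError):
    """The output of an external energy engine could not be parsed."""


class FixtureError(VgscanError):
    """The synthetic-complex generator was asked for an infeasible geometry."""
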