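"""Exception hierarchy shared across the pipeline stages."""


class SDARError(Exception):
    """Base class for all package errors."""


class StructureParseError(SDARError, IOError):
    """A structure file could not be read or parsed."""


class DegenerateInputError(SDARError, ValueError):
    """Input is syntactically valid but unusable (e.g. 2D-only coordinates)."""


class ValidationError(SDARError, ValueError):
    """A manifest or configuration violates its contract."""


class IncompleteAssignmentError(SDARError, ValueError):
    """A shift table does not cover every C/N atom of a molecule."""

    def __init__(self, molecule_id: str, missing_indices):
        self.molecule_id = molecule_id
        self.missing_indices = sorted(missing_indices)
        super().__init__(
            f"molecule {molecule_id!r}: no shift for atom indices "
            f"{self.missing_indices} (0-based)"
        )


class ContractError(SDARError, ValueError):
    """Dimension or interface mismatch between pipeline stages."""


class TrainingFailureError(SDARError, RuntimeError):
    """MLP training diverged even after the learning-rate restart."""


class GenerationError(SDARError, RuntimeError):
    """Synthetic-data rejection sampling exhausted its retry budget."""
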