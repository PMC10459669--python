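"""Exception hierarchy for the equivs pipeline."""


class EquiVSError(Exception):
    """Base class for all equivs errors."""


class ParseError(EquiVSError):
    """SMILES (or other structure input) could not be parsed."""


class EmptyMoleculeError(EquiVSError):
    """Molecule has no heavy atoms left after fragment removal."""


class EmbeddingError(EquiVSError):
    """3D embedding failed after the bounded retry policy."""


class ForceFieldError(EquiVSError):
    """MMFF94 setup failed (e.g. unparameterized atom type)."""


class FormatError(EquiVSError):
    """Malformed or empty SDF/CSV input."""


class ConsistencyError(EquiVSError):
    """Atom ordering mismatch between topology and coordinates."""


class ShapeError(EquiVSError):
    """Tensor shapes inconsistent with the model contract."""


class EmptyBatchError(EquiVSError):
    """A loss was requested on an empty batch."""


class EmptyInputError(EquiVSError):
    """An aggregation was requested on an empty value list."""


class SplitError(EquiVSError):
    """Dataset too small to split into train/valid/test."""


class TrainingDivergedError(EquiVSError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class AttentionUnavailableError(EquiVSError):
    """Attention coefficients requested from a variant without attention."""


class GenerationError(EquiVSError):
    """Synthetic task generator cannot satisfy the request."""
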