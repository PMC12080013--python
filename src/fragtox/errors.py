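"""Typed failures raised across the package.

Parsing and embedding failures subclass :class:`MoleculeError` so dataset
loaders can catch one type and count the molecule as dropped.
"""


class FragtoxError(Exception):
    """Base class for all package errors."""


class MoleculeError(FragtoxError):
    """A molecule could not be turned into a usable record."""


class ParseFailure(MoleculeError):
    """SMILES string could not be parsed."""


class SanitizeFailure(MoleculeError):
    """Molecule parsed but failed valence/aromaticity sanitization."""


class EmbedFailure(MoleculeError):
    """No 3D conformer could be generated."""


class MissingColumn(FragtoxError):
    """Requested CSV column not present."""


class AllMoleculesDropped(FragtoxError):
    """Every row of an input table failed parsing or embedding."""


class EmptyDataset(FragtoxError):
    """Operation requires at least one molecule."""


class PartitionError(FragtoxError):
    """A fragment assignment is not a valid partition of the atoms."""


class ConfigError(FragtoxError):
    """Invalid model or training configuration."""


class ShapeMismatch(FragtoxError):
    """Array arguments have inconsistent shapes."""


class LengthMismatch(FragtoxError):
    """Gradient vectors have different lengths."""


class LayerOutOfRange(FragtoxError):
    """Requested attention layer does not exist."""


class NonFiniteLoss(FragtoxError):
    """Training loss became NaN or infinite."""


class NoDefinedTask(FragtoxError):
    """AUROC is undefined for every task on the given split."""


class InfeasibleSpec(FragtoxError):
    """A fixture specification cannot be satisfied by the building blocks."""
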