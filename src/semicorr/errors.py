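"""Exception types shared across the package."""


class SemicorrError(Exception):
    """Base class for all package-specific errors."""


class MalformedSmilesError(SemicorrError, ValueError):
    """A SMILES string cannot be decomposed into attributes."""


class EmptyInputError(SemicorrError, ValueError):
    """An operation received an empty input where content is required."""


class SubsetLabelError(SemicorrError, ValueError):
    """A frequency table was built on the wrong subset for this operation."""


class SingleClassError(SemicorrError, ValueError):
    """A dataset contains only one activity class and cannot be split or fit."""


class DegenerateFitError(SemicorrError, ValueError):
    """The latent regression is undefined (constant descriptor or zero slope)."""


class UndefinedCorrelationError(SemicorrError, ValueError):
    """Pearson correlation is undefined because one vector is constant."""
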