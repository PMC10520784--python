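"""Exception types raised across the pipeline."""


class RehoSeedError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RehoSeedError):
    """Input file is not in the expected format (e.g. not a 4D NIfTI)."""


class GeometryError(RehoSeedError):
    """Image grids disagree in shape or affine beyond tolerance."""


class ParameterError(RehoSeedError):
    """A numeric parameter is out of its valid range."""


class SeedError(RehoSeedError):
    """A seed region is empty or lies outside the mask."""


class DesignError(RehoSeedError):
    """The group/covariate design matrix is rank deficient."""


class InputError(RehoSeedError):
    """An input container violates a precondition (empty mask, empty set...)."""


class SpecError(RehoSeedError):
    """A synthetic cohort specification is inconsistent."""
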