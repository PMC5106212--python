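"""Exception hierarchy shared across the package."""


class PcdhkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PcdhkitError):
    """A coordinate or sequence file could not be parsed."""


class EmptyStructureError(PcdhkitError):
    """A structure contains no polymer atoms."""


class AnnotationError(PcdhkitError):
    """A domain annotation is missing, inconsistent, or does not cover a request."""


class GeometryError(PcdhkitError):
    """Degenerate geometry: too few points, collinear/planar sets, no surviving pairs."""


class SelectionError(PcdhkitError):
    """Invalid residue/chain selection (overlap, unknown chain, ...)."""


class RadiiError(PcdhkitError):
    """An element has no radius in the active radii set and no fallback is allowed."""


class ParameterError(PcdhkitError):
    """Invalid user parameter (non-monotone bin edges, rates outside [0,1], ...)."""


class AlignmentError(PcdhkitError):
    """Sequence alignment inputs are inconsistent (unequal lengths, missing reference)."""


class CoverageError(PcdhkitError):
    """A requested position is absent from a logo or numbering map."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)


class MappingError(CoverageError):
    """A residue could not be mapped onto the reference numbering."""


class RulesError(PcdhkitError):
    """A residue is outside the compatibility rule tables."""


class PhysicsError(PcdhkitError):
    """Unphysical sedimentation parameters (non-buoyant species, negative K, ...)."""


class ConvergenceError(PcdhkitError):
    """A nonlinear fit failed to converge after all restarts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GenerationError(PcdhkitError):
    """A synthetic-data generator was asked for impossible geometry."""


class ConfigError(PcdhkitError):
    """A run configuration failed schema validation or references missing inputs."""
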