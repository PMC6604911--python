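"""Exception hierarchy shared across the package."""


class DnapatiteError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DnapatiteError):
    """Inconsistent crystal specification (e.g. non-closing symmetry ops)."""


class OccupancyError(DnapatiteError):
    """Partial occupancies that do not resolve to integer site counts."""


class InputError(DnapatiteError):
    """Structurally invalid input to an operation."""


class CarvingError(DnapatiteError):
    """A mineral group clashing with the guest has no vacant border site."""


class GeometryError(DnapatiteError):
    """Guest does not fit the pore."""


class ParameterizationError(DnapatiteError):
    """A force-field parameter lookup failed; message names the type."""


class MinimizationError(DnapatiteError):
    """Energy minimization diverged."""


class IntegrationError(DnapatiteError):
    """Molecular dynamics blew up; message names the step."""


class PackingError(DnapatiteError):
    """Requested box contents cannot be packed at the clash threshold."""


class PlaneNotFoundError(DnapatiteError):
    """No phosphate 4-tuple matches the target plane within tolerance."""


class FitError(DnapatiteError):
    """Rigid lattice fit residual above tolerance."""


class ParseError(DnapatiteError):
    """Malformed structure file; message carries the line number."""
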