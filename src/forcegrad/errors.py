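"""Exception hierarchy."""


class ForcegradError(Exception):
    """Base class for all package errors."""


class UnsupportedResidueError(ForcegradError):
    """Residue code outside the 20 standard amino acids."""


class DegenerateInputError(ForcegradError):
    """Input too small or geometrically degenerate to process."""


class DegenerateFrameError(ForcegradError):
    """Three reference atoms are (near-)collinear; no frame can be built."""


class BuildError(ForcegradError):
    """All-atom construction failed (missing angle, bad topology, ...)."""


class PlacementError(ForcegradError):
    """Hydrogen placement failed (missing parent or reference atom)."""


class MeasurementError(ForcegradError):
    """Internal-coordinate measurement failed."""


class CapabilityError(ForcegradError):
    """An optional backend (e.g. an MD engine) is not available."""


class PDBFormatError(ForcegradError):
    """A PDB file violates the subset of the format this package accepts."""
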