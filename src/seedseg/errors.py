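"""Exception taxonomy shared by all pipeline stages.

Grouped so the CLI can map families to distinct exit codes:
parameter/format errors (bad configuration), I/O errors, and
degenerate-input errors (inputs the algorithm cannot act on).
"""


class SeedSegError(Exception):
    """Base class for all seedseg errors."""


class ParameterError(SeedSegError, ValueError):
    """A configuration value violates its documented invariant."""


class FormatError(SeedSegError, ValueError):
    """An image does not have the expected layout (e.g. not 3-channel RGB)."""


class GeometryError(SeedSegError, ValueError):
    """A box or region is degenerate (zero width/height, out of bounds)."""


class DegenerateHistogramError(SeedSegError):
    """Intensity histogram has fewer than two occupied bins; no threshold exists."""


class EmptyReferenceError(SeedSegError):
    """Contact judgment asked for a scene-median reference on an empty box list."""


class UndefinedAccuracyError(SeedSegError):
    """Accuracy requested over zero segmented outputs."""


class CapacityError(SeedSegError):
    """Synthetic scene packing failed: requested seeds do not fit the canvas."""


class DatasetError(SeedSegError, OSError):
    """Dataset root missing or unreadable."""
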