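"""Exception hierarchy."""


class LidarPhenoError(Exception):
    """Base class for all package errors."""


class FileFormatError(LidarPhenoError):
    """Malformed or unsupported point-cloud file."""


class InfeasibleLeafAreaError(LidarPhenoError):
    """A requested per-layer leaf area cannot fit inside the cell footprint."""

    def __init__(self, layer: int, message: str):
        self.layer = layer
        super().__init__(f"layer {layer}: {message}")


class GridCoverageError(LidarPhenoError):
    """The segmentation grid does not cover all vegetation points."""

    def __init__(self, n_orphans: int, message: str | None = None):
        self.n_orphans = n_orphans
        super().__init__(
            message or f"{n_orphans} vegetation point(s) fall outside the grid"
        )
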