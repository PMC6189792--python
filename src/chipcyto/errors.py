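"""Exception types shared across the pipeline stages."""


class ChipCytoError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(ChipCytoError):
    """Raised when nuclei cannot be placed in the requested field geometry."""


class UnusableFieldError(ChipCytoError):
    """Raised when a field has no background pixels to estimate from."""


class UnimodalHistogramError(ChipCytoError):
    """Raised when no G1/G2 peak pair satisfying the 2N:4N ratio constraint
    exists — the failure mode of over-stained (saturated) samples."""


class InfeasibleMixtureError(ChipCytoError):
    """Raised when no non-negative cell-cycle mixture reproduces the requested
    gated phase fractions."""


class InputError(ChipCytoError):
    """Raised for missing or unreadable pipeline inputs."""


class QCFailureError(ChipCytoError):
    """Raised in strict mode when a field fails acquisition QC."""
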