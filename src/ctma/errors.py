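"""Exception types shared across the package."""


class CTMAError(Exception):
    """Base class for all package-specific errors."""


class MeshValidationError(CTMAError):
    """A mesh violates a structural invariant (non-finite vertices, bad indices, too small)."""


class STLParseError(CTMAError):
    """An STL file could not be parsed; the message names the byte offset when known."""


class TransformValidationError(CTMAError):
    """A matrix is not a proper rigid transform (orthonormal, det +1)."""


class SegmentationError(CTMAError):
    """Seeded region growing failed (seed below threshold, empty region, ...)."""


class RegistrationError(CTMAError):
    """Registration preconditions violated (too few points, degenerate geometry)."""


class OrientationError(CTMAError):
    """Mirrored/unmirrored mix-up: proximal registration needed a rotation > 90 degrees."""


class FixtureError(CTMAError):
    """Packaged cohort fixture failed its self-check (corrupt packaging)."""
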