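"""Exception types shared across the package."""


class CgmSensError(Exception):
    """Base class for all package errors."""


class ValidationError(CgmSensError, ValueError):
    """An input value violates a documented invariant."""


class MissingMarkerError(CgmSensError, KeyError):
    """A required marker label is absent from a trial."""

    def __init__(self, *labels: str):
        self.labels = labels
        super().__init__(f"missing required marker(s): {', '.join(labels)}")


class DegenerateGeometryError(CgmSensError, ValueError):
    """Marker geometry does not admit the requested construction.

    Raised e.g. for collinear points where a plane is needed, or a chord
    radius not smaller than the proximal-to-lateral distance.  When the
    failure occurs at a specific frame of a trial the frame index is
    carried in ``frame``.
    """

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        if frame is not None:
            message = f"{message} (frame {frame})"
        super().__init__(message)
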