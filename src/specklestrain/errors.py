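"""Exception types shared across the pipeline."""


class SpecError(ValueError):
    """An invalid generator / ROI / tracker specification."""


class PlacementError(SpecError):
    """An ROI segment that does not fit inside the image."""


class TrackingLostError(RuntimeError):
    """Fewer than two reliable points survive in some frame."""


class MissingDataError(ValueError):
    """A subject x muscle x level cell has too few trials (or none)."""
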