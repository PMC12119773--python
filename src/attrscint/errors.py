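"""Exception types shared across the pipeline."""


class AttrscintError(ValueError):
    """Base class for domain errors."""


class PhantomSizingError(AttrscintError):
    """Grid too small to place the phantom organs."""


class EmptyMaskError(AttrscintError):
    """A segmentation mask contains no foreground; callers apply a fallback."""


class AlignmentError(AttrscintError):
    """Two grids that must share shape/spacing do not."""
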