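"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (validation -> 2, I/O -> 3,
data integrity -> 4); library users catch them directly.
"""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class DimensionalityError(ValidationError):
    """A volume does not reduce to three non-singleton dimensions."""


class GridMismatchError(ValidationError):
    """Image and mask do not share a voxel grid."""

    def __init__(self, image_shape, mask_shape):
        self.image_shape = tuple(image_shape)
        self.mask_shape = tuple(mask_shape)
        super().__init__(
            f"mask grid {self.mask_shape} does not match image grid {self.image_shape}"
        )


class DataIntegrityError(RuntimeError):
    """A packaged fixture failed its checksum or shape contract."""
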