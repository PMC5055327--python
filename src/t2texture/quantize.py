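"""Global 256-level gray-scale quantization.

T2-weighted images have a well-anchored dynamic range: air/bone pins the
minimum near zero and cerebrospinal fluid pins the maximum. Rescaling the
*whole image* (not the VOI) to 256 levels therefore puts every case on a
comparable 8-bit scale, which is what makes both the VOI entropy and the
rim gradient magnitudes directly comparable across patients.

The mapping is ``level(v) = floor(255 * (v - min) / (max - min) + 0.5)``
(round half up), so the image minimum maps exactly to 0 and the maximum to
255. A constant image degenerates to all-zero levels with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import IntensityVolume

__all__ = ["QuantizedVolume", "quantize_to_256", "N_LEVELS"]

N_LEVELS = 256

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantizedVolume:
    """3D array of integer gray levels 0..255 plus the source intensity range."""

    data: np.ndarray
    source_min: float
    source_max: float

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D level array, got shape {data.shape}")
        if data.size and (data.min() < 0 or data.max() > N_LEVELS - 1):
            raise ValueError("levels outside 0..255")
        if self.source_min > self.source_max:
            raise ValueError("source_min exceeds source_max")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def quantize_to_256(volume: IntensityVolume) -> QuantizedVolume:
    """Rescale a volume to integer levels 0..255 using whole-image min/max."""
    data = volume.data
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        logger.warning(
            "constant volume (value %.6g): all levels set to 0; entropy will be 0", lo
        )
        levels = np.zeros(data.shape, dtype=np.uint8)
        return QuantizedVolume(data=levels, source_min=lo, source_max=hi)
    scaled = (N_LEVELS - 1) * (data - lo) / (hi - lo)
    levels = np.clip(np.floor(scaled + 0.5), 0, N_LEVELS - 1).astype(np.uint8)
    return QuantizedVolume(data=levels, source_min=lo, source_max=hi)
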