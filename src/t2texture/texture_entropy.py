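"""Shannon entropy of the 256-level VOI histogram, and the per-case pipeline.

Entropy here is first-order texture: the gray-level histogram over the VOI
is taken on the fixed, globally quantized 256-level scale and summarized as
``S = -sum_i p_i log2 p_i`` (bits, 0..8). A lesion whose voxels concentrate
on few levels — visually homogeneous — scores low; a lesion spreading over
many levels — visually heterogeneous — scores high. Bins are the 256
predefined levels, never adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, ValidationError
from .image_io import IntensityVolume, VOIMask
from .prewitt_edge import edge_metrics, extract_rim, prewitt_magnitude
from .quantize import N_LEVELS, QuantizedVolume, quantize_to_256

__all__ = [
    "Histogram256",
    "TextureMetrics",
    "voi_histogram",
    "shannon_entropy",
    "case_entropy",
    "compute_case_metrics",
]

MAX_ENTROPY_BITS = 8.0


@dataclass(frozen=True)
class Histogram256:
    """Level counts over the 256 gray levels inside a VOI."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValidationError(f"expected {N_LEVELS} bins, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValidationError("negative bin count")
        if counts.sum() == 0:
            raise ValidationError("empty histogram")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.total


@dataclass(frozen=True)
class TextureMetrics:
    """Per-case texture record: entropy (bits) and rim edge statistics."""

    entropy: float
    edge_mean: float
    edge_median: float

    def __post_init__(self):
        if not (0.0 <= self.entropy <= MAX_ENTROPY_BITS + 1e-9):
            raise ValidationError(f"entropy {self.entropy} outside [0, 8] bits")
        if self.edge_mean < 0 or self.edge_median < 0:
            raise ValidationError("edge statistics must be non-negative")


def voi_histogram(qvol: QuantizedVolume, mask: VOIMask) -> Histogram256:
    """Tally the quantized levels of the masked voxels into 256 bins."""
    if qvol.shape != mask.shape:
        raise GridMismatchError(qvol.shape, mask.shape)
    mask.require_nonempty()
    counts = np.bincount(qvol.data[mask.data], minlength=N_LEVELS)
    return Histogram256(counts=counts)


def shannon_entropy(hist: Histogram256) -> float:
    """S = -sum p_i log2 p_i in bits, with the convention 0*log2(0) = 0."""
    p = hist.frequencies
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def case_entropy(volume: IntensityVolume, mask: VOIMask) -> float:
    """Entropy of one case: global 256-level quantization, then VOI histogram."""
    return shannon_entropy(voi_histogram(quantize_to_256(volume), mask))


def compute_case_metrics(
    volume: IntensityVolume, mask: VOIMask, slice_axis: int = 2
) -> TextureMetrics:
    """Run the full per-case pipeline on an image/VOI pair.

    One global quantization feeds both branches: the VOI histogram entropy,
    and the Prewitt gradient sampled on the one-voxel rim of the VOI.
    """
    if volume.shape != mask.shape:
        raise GridMismatchError(volume.shape, mask.shape)
    qvol = quantize_to_256(volume)
    entropy = shannon_entropy(voi_histogram(qvol, mask))
    grad = prewitt_magnitude(qvol, slice_axis=slice_axis)
    rim = extract_rim(mask, slice_axis=slice_axis)
    edge_mean, edge_median = edge_metrics(grad, rim)
    return TextureMetrics(entropy=entropy, edge_mean=edge_mean, edge_median=edge_median)
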