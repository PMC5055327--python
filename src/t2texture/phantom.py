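"""Synthetic lesion phantoms with dial-in heterogeneity and border sharpness.

No clinical MRIs accompany the published cohort, so the image pipeline is
exercised on phantoms that emulate what the two metrics actually measure on
a T2-weighted image:

* a roughly ellipsoidal hyperintense lesion on a darker background;
* intra-lesion diversity controlled by ``k`` intensity components (each
  lesion voxel draws one component mean, plus optional Gaussian noise) —
  the heterogeneity knob that entropy should track (about log2 k bits for
  equal, well-separated, noise-free components);
* boundary blur controlled by a Gaussian of width ``border_blur_sigma``
  applied to the whole image — the sharpness knob that the rim edge
  statistics should track inversely;
* an optional small unblurred blob at a fixed high intensity, playing the
  role cerebrospinal fluid plays on real T2WI: it pins the global maximum
  so the 256-level rescale is anchored identically across specs.

The VOI mask is the exact pre-blur ellipsoid — the analogue of manual
segmentation of the visible lesion — and depends only on geometry, never on
the intensity knobs. Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import IntensityVolume, VOIMask

__all__ = ["PhantomSpec", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image/VOI pair.

    Intensities are arbitrary MR-like units; the defaults give a mildly
    noisy, mildly blurred single-component lesion occupying roughly a sixth
    of a 64 x 64 x 16 grid.
    """

    grid: tuple[int, int, int] = (64, 64, 16)
    center: tuple[float, float, float] | None = None  # defaults to grid center
    semi_axes: tuple[float, float, float] = (20.0, 20.0, 6.0)
    background_level: float = 30.0
    component_means: tuple[float, ...] = (180.0,)
    component_weights: tuple[float, ...] | None = None  # defaults to equal
    intra_component_noise_sd: float = 5.0
    border_blur_sigma: float = 1.0
    csf_center: tuple[float, float, float] = (5.0, 5.0, 8.0)
    csf_radius: float = 2.5
    csf_level: float = 255.0
    include_csf: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.component_means) < 1:
            raise ValidationError("at least one intensity component is required")
        if self.border_blur_sigma < 0:
            raise ValidationError("border_blur_sigma must be >= 0")
        if self.intra_component_noise_sd < 0:
            raise ValidationError("intra_component_noise_sd must be >= 0")
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi-axes must be positive")
        center = self.resolved_center
        for c, a, dim in zip(center, self.semi_axes, self.grid):
            if c - a < 0 or c + a > dim - 1:
                raise ValidationError(
                    f"lesion (center {center}, semi-axes {self.semi_axes}) "
                    f"exceeds grid {self.grid}"
                )
        weights = self.resolved_weights
        if len(weights) != len(self.component_means):
            raise ValidationError("one weight per component is required")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("component weights must be non-negative and sum to 1")

    @property
    def resolved_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple((d - 1) / 2.0 for d in self.grid)

    @property
    def resolved_weights(self) -> tuple[float, ...]:
        if self.component_weights is not None:
            return self.component_weights
        k = len(self.component_means)
        return tuple([1.0 / k] * k)


def _ellipsoid(grid, center, semi_axes) -> np.ndarray:
    idx = np.indices(grid, dtype=np.float64)
    dist2 = sum(
        ((idx[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3)
    )
    return dist2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, VOIMask]:
    """Render the phantom image and its VOI mask.

    Pipeline: paint background, draw one component per lesion voxel
    (categorical by weight) plus Gaussian noise, blur the whole image with
    ``border_blur_sigma``, then stamp the unblurred high-intensity blob.
    """
    rng = np.random.default_rng(spec.seed)
    lesion = _ellipsoid(spec.grid, spec.resolved_center, spec.semi_axes)
    if not lesion.any():
        raise ValidationError("lesion ellipsoid contains no voxels")

    image = np.full(spec.grid, spec.background_level, dtype=np.float64)
    n_vox = int(lesion.sum())
    means = np.asarray(spec.component_means, dtype=np.float64)
    assignment = rng.choice(len(means), size=n_vox, p=spec.resolved_weights)
    values = means[assignment]
    if spec.intra_component_noise_sd > 0:
        values = values + rng.normal(0.0, spec.intra_component_noise_sd, size=n_vox)
    image[lesion] = values

    if spec.border_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.border_blur_sigma)

    if spec.include_csf:
        blob = _ellipsoid(
            spec.grid, spec.csf_center, (spec.csf_radius,) * 3
        )
        if (blob & lesion).any():
            raise ValidationError("csf blob overlaps the lesion")
        image[blob] = spec.csf_level

    return IntensityVolume(data=image), VOIMask(data=lesion)
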