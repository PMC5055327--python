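"""Compute the three texture metrics for one image/VOI pair.

Builds a synthetic lesion, round-trips it through NIfTI like a real case,
and runs the full pipeline: global 256-level quantization, VOI histogram
entropy, Prewitt filtering and rim edge statistics.
"""

import tempfile
from pathlib import Path

from t2texture import (
    PhantomSpec,
    compute_case_metrics,
    generate_phantom,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

spec = PhantomSpec(seed=7, component_means=(140.0, 200.0), border_blur_sigma=1.0)
volume, mask = generate_phantom(spec)

with tempfile.TemporaryDirectory() as tmp:
    image_path = Path(tmp) / "case_image.nii.gz"
    mask_path = Path(tmp) / "case_voi.nii.gz"
    write_volume(volume, image_path)
    write_mask(mask, mask_path)

    volume = read_volume(image_path)
    mask = read_mask(mask_path, reference=volume)

metrics = compute_case_metrics(volume, mask)
print(f"VOI voxels:  {mask.n_voxels}")
print(f"entropy:     {metrics.entropy:.4f} bits")
print(f"edge mean:   {metrics.edge_mean:.4f}")
print(f"edge median: {metrics.edge_median:.4f}")
print()
print("The two intensity components plus per-voxel noise and mild blur spread")
print("the VOI histogram over many of the 256 levels, giving an entropy in the")
print("range real lesions show (about 5-7 bits). The edge values are the")
print("mean/median Prewitt gradient (levels per pixel step) on the one-voxel")
print("rim of the lesion — higher means a sharper border.")
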