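"""Phantom generation for desk-scale runs of the full pipeline.

Two families of phantoms mirror the structure of the CT data the network is
built for, without claiming anatomical realism:

* **nodule phantoms** (binary): small bright elliptical lesions with
  anisotropic Gaussian intensity profiles on a low-frequency textured
  background, like cropped lung-window patches centred on a nodule;
* **organ/tumor phantoms** (3 classes): one large "organ" region containing
  a much smaller "tumor" region, reproducing the strong organ-vs-tumor size
  imbalance of liver/kidney tumor data.

Every sample is fully determined by its seed.  Lesion masks are the
half-maximum support of the intensity profile, which gives non-trivial
curved boundaries for the Hausdorff metrics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import LabeledSlice, write_manifest, write_png


class GenerationError(RuntimeError):
    """Lesion placement failed after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the defaults define the study conditions."""

    side: int = 128
    n_lesions: int = 1
    lesion_radius_range: tuple = (4.0, 12.0)
    intensity_contrast: float = 0.45
    noise_sd: float = 0.08
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.lesion_radius_range[0] <= 0 or self.lesion_radius_range[1] >= self.side / 4:
            raise ValueError(
                f"lesion radii must lie in (0, side/4), got {self.lesion_radius_range}"
            )
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")


def _background(rng: np.random.Generator, side: int) -> np.ndarray:
    """Low-frequency smoothed noise field in [0.05, 0.35]."""
    field = gaussian_filter(rng.standard_normal((side, side)), sigma=side / 16)
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)
    return (0.05 + 0.30 * field).astype(np.float64)


def _gaussian_blob(side, centre, radii, theta):
    """Anisotropic Gaussian profile with half-max at the given radii."""
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    dr, dc = rr - centre[0], cc - centre[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    # exp(-log(2) * q) so the profile crosses 0.5 exactly at the ellipse
    q = (u / radii[0]) ** 2 + (v / radii[1]) ** 2
    return np.exp(-np.log(2.0) * q)


def make_nodule_phantom(spec: PhantomSpec) -> LabeledSlice:
    """Binary phantom: bright lesions (label 1) on textured background."""
    if spec.n_classes != 2:
        raise ValueError("nodule phantoms are binary; use n_classes=2")
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    image = _background(rng, side)
    mask = np.zeros((side, side), dtype=np.int64)

    lo, hi = spec.lesion_radius_range
    placed = 0
    for _ in range(50 * max(spec.n_lesions, 1)):
        if placed == spec.n_lesions:
            break
        radii = rng.uniform(lo, hi, size=2)
        margin = int(np.ceil(max(radii))) + 2
        centre = rng.uniform(margin, side - margin, size=2)
        theta = rng.uniform(0, np.pi)
        profile = _gaussian_blob(side, centre, radii, theta)
        support = profile >= 0.5
        if (mask[support] != 0).any():
            continue  # overlap; retry
        image += spec.intensity_contrast * profile
        mask[support] = 1
        placed += 1
    if placed < spec.n_lesions:
        raise GenerationError(
            f"could only place {placed}/{spec.n_lesions} lesions on a {side}x{side} phantom"
        )
    image += spec.noise_sd * rng.standard_normal((side, side))
    image = np.clip(image, 0.0, 1.0)
    return LabeledSlice(image=image, mask=mask, source_id=f"nodule_{spec.seed}")


def make_organ_tumor_phantom(spec: PhantomSpec) -> LabeledSlice:
    """3-class phantom: large organ (label 1) containing a small tumor (label 2)."""
    if spec.n_classes != 3:
        raise ValueError("organ/tumor phantoms need n_classes=3")
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    image = _background(rng, side)
    mask = np.zeros((side, side), dtype=np.int64)

    organ_r = rng.uniform(0.18, 0.26) * side
    organ_centre = np.array([side / 2, side / 2]) + rng.uniform(-0.06, 0.06, 2) * side
    organ_theta = rng.uniform(0, np.pi)
    organ_radii = organ_r * rng.uniform(0.8, 1.2, 2)
    organ_profile = _gaussian_blob(side, organ_centre, organ_radii, organ_theta)
    organ = organ_profile >= 0.5
    image += 0.30 * organ_profile
    mask[organ] = 1

    # tumor strictly inside the organ ellipse: small radius, bounded offset
    tumor_r = rng.uniform(0.12, 0.30) * min(organ_radii)
    max_off = max(min(organ_radii) - tumor_r - 2.0, 0.0)
    phi = rng.uniform(0, 2 * np.pi)
    off = rng.uniform(0, 0.6) * max_off
    tumor_centre = organ_centre + off * np.array([np.cos(phi), np.sin(phi)])
    tumor_profile = _gaussian_blob(side, tumor_centre, (tumor_r, tumor_r), 0.0)
    tumor = (tumor_profile >= 0.5) & organ  # containment by construction
    image += 0.25 * tumor_profile
    mask[tumor] = 2

    image += spec.noise_sd * rng.standard_normal((side, side))
    image = np.clip(image, 0.0, 1.0)
    return LabeledSlice(image=image, mask=mask, source_id=f"organ_{spec.seed}")


def make_phantom(spec: PhantomSpec) -> LabeledSlice:
    if spec.n_classes == 2:
        return make_nodule_phantom(spec)
    return make_organ_tumor_phantom(spec)


def make_phantom_set(n: int, spec: PhantomSpec) -> list:
    """n phantoms with per-item seeds derived as ``spec.seed + i``."""
    return [make_phantom(replace(spec, seed=spec.seed + i)) for i in range(n)]


def make_dataset(n: int, spec: PhantomSpec, out_dir) -> Path:
    """Write ``n`` PNG image/mask pairs plus a CSV manifest; returns its path."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, sl in enumerate(make_phantom_set(n, spec)):
            img_name, mask_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
            write_png(out_dir / img_name, sl.image)
            write_png(out_dir / mask_name, sl.mask, is_mask=True)
            rows.append(
                {"source_id": sl.source_id, "image": img_name, "mask": mask_name,
                 "n_classes": spec.n_classes}
            )
        manifest = out_dir / "manifest.csv"
        write_manifest(manifest, rows)
    except OSError as exc:
        raise IOError(f"cannot write dataset under {out_dir}: {exc}") from exc
    return manifest


def dataset_fingerprint(manifest_path) -> str:
    """SHA-256 over the manifest and every referenced file (determinism checks)."""
    manifest_path = Path(manifest_path)
    h = hashlib.sha256(manifest_path.read_bytes())
    import csv as _csv

    with open(manifest_path, newline="") as fh:
        for row in _csv.DictReader(fh):
            h.update((manifest_path.parent / row["image"]).read_bytes())
            h.update((manifest_path.parent / row["mask"]).read_bytes())
    return h.hexdigest()
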