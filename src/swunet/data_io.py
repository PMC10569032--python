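"""Readers, writers and preprocessing for CT slices and annotations.

Covers the steps that turn raw challenge-style data into network inputs:
per-image min-max normalization into [0, 1], conversion of world-coordinate
sphere annotations (series id, x/y/z in mm, diameter) into voxel masks,
nodule-centred 128x128 cropping, bilinear/nearest resampling, and seeded
80/10/10 dataset splitting.  Volumes are read through SimpleITK (MetaImage)
and nibabel (NIfTI); 2-D images and label masks travel as 8-bit PNG with a
CSV manifest.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from skimage.transform import resize


class OutOfBoundsError(ValueError):
    """An annotation centre falls outside the volume."""


@dataclass
class LabeledSlice:
    """One 2-D training example: intensity image in [0,1] plus label mask."""

    image: np.ndarray
    mask: np.ndarray
    source_id: str = ""
    pixel_spacing: float | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ"
            )
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")


@dataclass(frozen=True)
class NoduleAnnotation:
    """A spherical lesion annotation in world (mm) coordinates."""

    series_id: str
    world_x: float
    world_y: float
    world_z: float
    diameter: float = 3.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")


@dataclass
class SplitPlan:
    train_ids: list = field(default_factory=list)
    val_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        all_ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split partitions overlap")

    def to_json(self) -> str:
        return json.dumps(
            {"train_ids": self.train_ids, "val_ids": self.val_ids,
             "test_ids": self.test_ids, "seed": self.seed}, indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def minmax_normalize(image) -> np.ndarray:
    """Per-image ``(x - min) / (max - min)``; a constant image maps to zeros."""
    x = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=np.float32)
    return ((x - lo) / (hi - lo)).astype(np.float32)


def annotation_to_mask(ann: NoduleAnnotation, origin, spacing, shape) -> np.ndarray:
    """Rasterize a sphere annotation into a binary voxel mask.

    ``origin``/``spacing`` are (x, y, z) in mm; ``shape`` is the (z, y, x)
    voxel array shape.  Voxel index = (world - origin) / spacing per axis.
    A diameter smaller than one voxel still marks the centre voxel.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    centre_xyz = (np.array([ann.world_x, ann.world_y, ann.world_z]) - origin) / spacing
    nz, ny, nx = shape
    for axis, (c, n) in enumerate(zip(centre_xyz, (nx, ny, nz))):
        if not 0 <= c <= n - 1:
            raise OutOfBoundsError(
                f"annotation centre axis {'xyz'[axis]}={c:.2f} outside [0, {n - 1}]"
            )
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    d2 = (
        ((xx - centre_xyz[0]) * spacing[0]) ** 2
        + ((yy - centre_xyz[1]) * spacing[1]) ** 2
        + ((zz - centre_xyz[2]) * spacing[2]) ** 2
    )
    mask = (d2 <= (ann.diameter / 2.0) ** 2).astype(np.uint8)
    if not mask.any():
        centre_idx = tuple(int(round(c)) for c in centre_xyz[::-1])
        mask[centre_idx] = 1
    return mask


def crop_patch(slice2d, centre_px, side: int = 128) -> np.ndarray:
    """Crop a ``side x side`` patch centred on ``centre_px`` (row, col).

    The window is clamped (never padded) at the borders, so the patch always
    lies inside the source and keeps real tissue context.
    """
    x = np.asarray(slice2d)
    h, w = x.shape[:2]
    if h < side or w < side:
        raise ValueError(f"source {h}x{w} smaller than patch side {side}; resample first")
    r0 = int(round(centre_px[0])) - side // 2
    c0 = int(round(centre_px[1])) - side // 2
    r0 = min(max(r0, 0), h - side)
    c0 = min(max(c0, 0), w - side)
    return x[r0 : r0 + side, c0 : c0 + side]


def resample_to(image, target_side: int = 128, is_mask: bool = False) -> np.ndarray:
    """Resize a 2-D image to ``target_side`` square.

    Bilinear for intensities; nearest-neighbour for label masks so no new
    label values appear.
    """
    x = np.asarray(image)
    if x.shape == (target_side, target_side):
        return x
    if is_mask:
        out = resize(x, (target_side, target_side), order=0, preserve_range=True,
                     anti_aliasing=False)
        return out.astype(x.dtype)
    out = resize(x.astype(float), (target_side, target_side), order=1, preserve_range=True,
                 anti_aliasing=x.shape[0] > target_side)
    return out.astype(np.float32)


def split_dataset(ids, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitPlan:
    """Seeded shuffle then 80/10/10 partition (remainder goes to train)."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 ids to split, got {len(ids)}")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return SplitPlan(
        train_ids=order[:n_train],
        val_ids=order[n_train : n_train + n_val],
        test_ids=order[n_train + n_val :],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_volume(path):
    """Read a MetaImage or NIfTI volume.

    Returns ``(array (z, y, x), origin (x, y, z) mm, spacing (x, y, z) mm)``.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".mhd") or name.endswith(".mha"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        return (
            sitk.GetArrayFromImage(img),
            np.array(img.GetOrigin()),
            np.array(img.GetSpacing()),
        )
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).T  # (x,y,z) -> (z,y,x)
        zooms = img.header.get_zooms()[:3]
        origin = img.affine[:3, 3]
        return data, np.asarray(origin, dtype=float), np.asarray(zooms, dtype=float)
    raise ValueError(f"unsupported volume format: {path.name}")


def write_mask_nifti(path, mask, spacing=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    mask = np.asarray(mask)
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(mask.T.astype(np.uint8), affine), str(path))


def read_annotations(path) -> list:
    """LUNA16-style CSV: ``seriesuid,coordX,coordY,coordZ,diameter_mm``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                NoduleAnnotation(
                    series_id=row["seriesuid"],
                    world_x=float(row["coordX"]),
                    world_y=float(row["coordY"]),
                    world_z=float(row["coordZ"]),
                    diameter=float(row.get("diameter_mm") or 3.0),
                )
            )
    return out


def write_png(path, array, is_mask: bool = False) -> None:
    """8-bit PNG; intensities are assumed in [0, 1], masks are raw labels."""
    if is_mask:
        imageio.imwrite(path, np.asarray(array).astype(np.uint8))
    else:
        x = np.clip(np.asarray(array, dtype=float), 0.0, 1.0)
        imageio.imwrite(path, np.round(x * 255).astype(np.uint8))


def read_png(path, is_mask: bool = False) -> np.ndarray:
    arr = np.asarray(imageio.imread(path))
    if is_mask:
        return arr.astype(np.int64)
    return (arr.astype(np.float32) / 255.0).astype(np.float32)


def write_manifest(path, rows) -> None:
    """CSV manifest with columns ``source_id,image,mask,n_classes``."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["source_id", "image", "mask", "n_classes"])
        writer.writeheader()
        writer.writerows(rows)


def load_manifest(path) -> list:
    """Read a manifest CSV into a list of :class:`LabeledSlice`."""
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            image = read_png(path.parent / row["image"])
            mask = read_png(path.parent / row["mask"], is_mask=True)
            out.append(LabeledSlice(image=image, mask=mask, source_id=row["source_id"]))
    return out


def slices_from_volume(volume, mask3d, series_id: str = "") -> list:
    """One :class:`LabeledSlice` per axial slice intersecting the 3-D mask."""
    volume = np.asarray(volume)
    mask3d = np.asarray(mask3d)
    out = []
    for z in np.flatnonzero(mask3d.reshape(mask3d.shape[0], -1).any(axis=1)):
        out.append(
            LabeledSlice(
                image=minmax_normalize(volume[z]),
                mask=mask3d[z].astype(np.int64),
                source_id=f"{series_id}_z{z}",
            )
        )
    return out
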