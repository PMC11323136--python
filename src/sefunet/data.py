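"""CT volume I/O, preprocessing and axial-slice handling.

Conventions: volumes are slice-major (D, H, W) with 0-based indexing and
the axial direction on the first axis; spacing is the matching (mm, mm,
mm) triple.  NIfTI files store (W, H, D) on disk and are transposed on
read/write.  CT intensities are windowed to the soft-tissue range
[-125, 275] HU and scaled linearly to [0, 1] before the network sees them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

HU_WINDOW = (-125.0, 275.0)


@dataclass
class CTVolume:
    voxels: np.ndarray          # (D, H, W) in HU (or [0,1] once normalized)
    spacing: tuple[float, float, float]
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a D x H x W array with D >= 1")
        if not np.isfinite(self.voxels).all():
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive values")


@dataclass
class LabelVolume:
    labels: np.ndarray          # (D, H, W) integer organ labels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    num_classes: int = 9

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a D x H x W array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0 or self.labels.max() >= self.num_classes:
            raise ValueError(
                f"labels outside the alphabet [0, {self.num_classes}): "
                f"found range [{self.labels.min()}, {self.labels.max()}]")


@dataclass
class SlicePair:
    """One preprocessed axial image in [0, 1] with its label mask."""
    image: np.ndarray
    label: np.ndarray
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        if self.image.shape != self.label.shape:
            raise ValueError("image and label shapes differ")
        if self.image.min() < -1e-6 or self.image.max() > 1 + 1e-6:
            raise ValueError("slice image must lie in [0, 1]")


# ---------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------

def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # disk order (W, H, D) -> memory order (D, H, W)
    return data.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]),
                                     float(zooms[0]))


def read_volume(path: str | Path) -> CTVolume:
    data, spacing = _load_nifti(path)
    return CTVolume(voxels=data.astype(np.float32), spacing=spacing,
                    case_id=Path(path).name.split(".")[0])


def read_labels(path: str | Path, num_classes: int = 9) -> LabelVolume:
    data, spacing = _load_nifti(path)
    return LabelVolume(labels=np.rint(data).astype(np.int16), spacing=spacing,
                       num_classes=num_classes)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(volume.voxels.transpose(2, 1, 0), affine), str(path))


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    affine = np.diag([labels.spacing[2], labels.spacing[1], labels.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16).transpose(2, 1, 0),
                             affine), str(path))


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def clip_normalize_hu(volume: CTVolume | np.ndarray,
                      lo: float = HU_WINDOW[0],
                      hi: float = HU_WINDOW[1]):
    """Truncate to [lo, hi] HU then scale linearly to [0, 1]."""
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    if isinstance(volume, CTVolume):
        out = (np.clip(volume.voxels, lo, hi) - lo) / (hi - lo)
        return CTVolume(out.astype(np.float32), volume.spacing, volume.case_id)
    arr = np.asarray(volume, np.float32)
    return ((np.clip(arr, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def extract_axial_slices(volume: CTVolume, labels: LabelVolume) -> list[SlicePair]:
    """One SlicePair per axial index, in order; expects a normalized volume."""
    if volume.voxels.shape != labels.labels.shape:
        raise ValueError("volume and label shapes differ")
    return [SlicePair(image=volume.voxels[k], label=labels.labels[k],
                      case_id=volume.case_id, slice_index=k)
            for k in range(volume.voxels.shape[0])]


def resize_image(image: np.ndarray, target: int, mode: str = "continuous"):
    """Resize to target x target; bilinear for images, nearest for labels."""
    if target < 1:
        raise ValueError("target size must be >= 1")
    if mode == "continuous":
        out = _sk_resize(image.astype(np.float32), (target, target), order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
        return out.astype(np.float32)
    if mode == "label":
        out = _sk_resize(image, (target, target), order=0, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        return np.rint(out).astype(image.dtype)
    raise ValueError("mode must be 'continuous' or 'label'")


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def augment_pair(pair: SlicePair, rng: np.random.Generator,
                 max_angle: float = 20.0) -> SlicePair:
    """Random flip / 90-degree rotation (p = 0.5), otherwise a random
    rotation in [-max_angle, max_angle] degrees with p = 0.5.

    Image and label always receive the identical transform; the image is
    interpolated bilinearly, the label nearest-neighbour.
    """
    img, lab = pair.image, pair.label
    if rng.random() < 0.5:
        op = rng.integers(0, 5)
        if op == 0:
            img, lab = img[::-1], lab[::-1]
        elif op == 1:
            img, lab = img[:, ::-1], lab[:, ::-1]
        else:  # 90-degree multiples
            k = int(op) - 1
            img, lab = np.rot90(img, k), np.rot90(lab, k)
        img, lab = np.ascontiguousarray(img), np.ascontiguousarray(lab)
    elif rng.random() < 0.5:
        angle = rng.uniform(-max_angle, max_angle)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="nearest")
    return SlicePair(image=img, label=lab, case_id=pair.case_id,
                     slice_index=pair.slice_index)


# ---------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------

@dataclass
class ManifestEntry:
    image_path: Path
    label_path: Path
    split: str  # "train" | "test"


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Plain-text manifest: one case per line, tab-separated
    ``image_path<TAB>label_path<TAB>split``; relative paths resolve
    against the manifest location."""
    path = Path(path)
    base = path.parent
    entries = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise IOError(f"malformed manifest line in {path}: {line!r}")
        img, lab, split = parts
        if split not in ("train", "test"):
            raise IOError(f"unknown split tag {split!r} in {path}")
        entries.append(ManifestEntry(base / img, base / lab, split))
    if not entries:
        raise IOError(f"manifest {path} lists no cases")
    return entries


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    base = Path(path).parent
    lines = []
    for e in entries:
        img = Path(e.image_path)
        lab = Path(e.label_path)
        try:
            img = img.relative_to(base)
            lab = lab.relative_to(base)
        except ValueError:
            pass
        lines.append(f"{img}\t{lab}\t{e.split}")
    Path(path).write_text("\n".join(lines) + "\n")
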