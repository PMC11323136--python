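"""Deterministic synthetic abdominal-CT phantom generator.

Each phantom is a soft-tissue body ellipse (~40 HU) on an air background
(-1000 HU) containing eight ellipsoidal "organs" with distinct mean
intensities spanning beyond the [-125, 275] HU display window, so the
preprocessing clip saturates at both ends.  Two organ pairs are placed
tangent to each other to mimic the adjacent/occluding-boundary challenge
of real abdominal anatomy.  Ellipsoids are geometric stand-ins, not
anatomy: the tests need class structure, adjacency and HU statistics, not
realistic shapes.  Later placements overwrite earlier ones at overlaps,
and everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (CTVolume, LabelVolume, ManifestEntry, write_labels,
                   write_manifest, write_volume)

#: default organ mean intensities in HU, labels 1..8; the extremes sit
#: outside the [-125, 275] window on purpose
DEFAULT_ORGAN_HU = (-150.0, -60.0, 20.0, 80.0, 140.0, 200.0, 260.0, 320.0)


class PhantomGenerationError(RuntimeError):
    """Raised when the requested organ radii cannot be placed in the body."""


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    organ_hu: tuple[float, ...] = DEFAULT_ORGAN_HU
    noise_sd: float = 10.0
    min_radius: int = 4
    max_radius: int = 10
    body_hu: float = 40.0
    air_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 1 for s in self.shape) or len(self.shape) != 3:
            raise ValueError("shape must be 3 positive integers")
        if len(self.organ_hu) != 8:
            raise ValueError("exactly 8 organ intensities are required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (1 <= self.min_radius <= self.max_radius):
            raise ValueError("need 1 <= min_radius <= max_radius")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, LabelVolume]:
    """Build one paired (HU volume, organ label volume) phantom."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    d, h, w = spec.shape
    vol = np.full(spec.shape, spec.air_hu, dtype=np.float32)
    lab = np.zeros(spec.shape, dtype=np.int16)

    body_radii = (d * 0.48, h * 0.42, w * 0.42)
    center = (d / 2, h / 2, w / 2)
    body = _ellipsoid_mask(spec.shape, center, body_radii)
    vol[body] = spec.body_hu

    # canonical organ centers in normalized body coordinates (y, x); the
    # entries for organs 2 and 6 are placeholders later snapped tangent to
    # organs 1 and 5 (the adjacency pairs)
    canon = [(-0.8, -0.7), (0.0, 0.0), (-0.8, 0.6), (0.0, 0.85),
             (0.8, -0.7), (0.0, 0.0), (0.8, 0.6), (0.0, -0.85)]
    span = min(h, w)
    rmax = min(spec.max_radius, int(span * 0.12))
    if rmax < spec.min_radius:
        raise PhantomGenerationError(
            f"radius range [{spec.min_radius}, {spec.max_radius}] does not fit "
            f"a {h}x{w} body cross-section")

    radii_list, centers = [], []
    for i in range(8):
        rr = int(rng.integers(spec.min_radius, rmax + 1))
        rz = max(2, int(rr * spec.spacing[1] / spec.spacing[0]))
        rz = min(rz, max(2, d // 3))
        radii_list.append((rz, rr, rr))
        cy = h / 2 + canon[i][0] * h * 0.35 + rng.uniform(-2, 2)
        cx = w / 2 + canon[i][1] * w * 0.35 + rng.uniform(-2, 2)
        cz = d / 2 + rng.uniform(-d * 0.12, d * 0.12)
        centers.append([cz, cy, cx])

    # adjacency: snap organ i+1 against organ i along +x with one voxel of
    # overlap, so the discretized masks share a boundary face
    for a, b in ((0, 1), (4, 5)):
        centers[b][0] = centers[a][0]
        centers[b][1] = centers[a][1]
        centers[b][2] = centers[a][2] + radii_list[a][2] + radii_list[b][2] - 1

    # paint the snapped partners (organs 2 and 6) last so no later organ can
    # carve them apart; overlap resolution stays "later paint wins"
    paint_order = (0, 2, 3, 4, 6, 7, 1, 5)
    for i in paint_order:
        radii, c = radii_list[i], centers[i]
        # keep the ellipsoid inside the volume bounds
        c = [min(max(ci, r + 1), s - r - 2)
             for ci, r, s in zip(c, radii, spec.shape)]
        if any(2 * r + 2 >= s for r, s in zip(radii, spec.shape)):
            raise PhantomGenerationError(
                f"organ {i + 1} radii {radii} too large for volume {spec.shape}")
        mask = _ellipsoid_mask(spec.shape, c, radii)
        if not mask.any():
            raise PhantomGenerationError(f"organ {i + 1} placement is empty")
        vol[mask] = spec.organ_hu[i]
        lab[mask] = i + 1      # later organs overwrite earlier at overlaps

    vol += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    case_id = f"phantom{spec.seed:04d}"
    return (CTVolume(vol, spec.spacing, case_id),
            LabelVolume(lab, spec.spacing))


def make_phantom_dataset(n_cases: int, base_seed: int, out_dir: str | Path,
                         spec: PhantomSpec | None = None) -> Path:
    """Write ``n_cases`` NIfTI pairs plus a manifest; the last ceil(n/4)
    cases form the test split.  Returns the manifest path."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_test = -(-n_cases // 4)
    entries = []
    for i in range(n_cases):
        case_spec = spec or PhantomSpec()
        case_spec = PhantomSpec(**{**case_spec.__dict__, "seed": base_seed + i})
        vol, lab = generate_phantom(case_spec)
        img_path = out_dir / f"{vol.case_id}_img.nii.gz"
        lab_path = out_dir / f"{vol.case_id}_lab.nii.gz"
        write_volume(vol, img_path)
        write_labels(lab, lab_path)
        split = "test" if i >= n_cases - n_test else "train"
        entries.append(ManifestEntry(img_path, lab_path, split))
    manifest = out_dir / "manifest.tsv"
    write_manifest(entries, manifest)
    return manifest
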