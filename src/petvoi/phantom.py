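"""Synthetic 3D PET phantoms with a co-registered label atlas.

The atlas places nine mutually exclusive regions on a regular grid: seven
cortical VOIs (frontal, parietal, medial temporal, lateral temporal, posterior
cingulate, precuneus, occipital) as blocks in the upper part of the volume, a
pons block low and medial (large enough to host the 16 mm reference box), and
background everywhere else. Phantom volumes invert the SUVr definition — each
region's mean activity is its target SUVr times the pons activity — so the
extraction pipeline can be validated against known truth.

Conventions: RAS+ affine, 0-based voxel indices, world units mm. Volumes are
written as gzipped NIfTI-1, the label map as a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .defaults import VOI_NAMES

PONS = "PONS"
BACKGROUND = "BACKGROUND"
REGION_NAMES = VOI_NAMES + (PONS, BACKGROUND)

# Fixed label encoding: background 0, VOIs 1..7, pons 8.
LABEL_CODES = {name: i + 1 for i, name in enumerate(VOI_NAMES)}
LABEL_CODES[PONS] = len(VOI_NAMES) + 1
LABEL_CODES[BACKGROUND] = 0

# Edge of the mid-pons reference box (mm); the pons block must exceed it in-plane.
REFERENCE_BOX_MM = 16.0


def _ras_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class LabelAtlas:
    """Integer label grid with its voxel geometry and label names."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        names = set(self.label_map.values())
        missing = set(REGION_NAMES) - names
        if missing:
            raise ValueError(f"label_map missing regions: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def code_of(self, name: str) -> int:
        for code, nm in self.label_map.items():
            if nm == name:
                return code
        raise KeyError(f"region {name!r} not in atlas")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.code_of(name)

    def voi_names(self) -> tuple[str, ...]:
        return tuple(n for n in VOI_NAMES if n in self.label_map.values())

    def region_voxel_counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == code))
                for code, name in sorted(self.label_map.items())}


@dataclass
class PetVolume:
    """3D activity grid sharing the geometry of its paired atlas."""

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D grid")
        if np.any(self.intensities < 0):
            raise ValueError("PET intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def check_compatible(self, atlas: LabelAtlas) -> None:
        if self.shape != atlas.shape:
            raise ValueError(f"volume shape {self.shape} != atlas shape {atlas.shape}")
        if not np.allclose(self.affine, atlas.affine):
            raise ValueError("volume and atlas affines differ")


def _block(center: tuple[int, int, int], half: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    return tuple(slice(c - h, c + h + 1) for c, h in zip(center, half))


def generate_atlas_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> LabelAtlas:
    """Build the deterministic nine-region block atlas.

    The pons block sits low and medial with in-plane extent strictly larger
    than the 16 mm reference box; the seven VOIs occupy the central portions
    of eight cells (2 z-slabs x 2x2 in-plane quadrants) above it, leaving the
    eighth cell as background.

    Raises ``ValueError`` when the grid cannot host all regions.
    """
    nx, ny, nz = grid_shape
    vx, vy, vz = voxel_size_mm
    if min(voxel_size_mm) <= 0:
        raise ValueError("voxel sizes must be positive")

    labels = np.zeros(grid_shape, dtype=np.int16)

    # pons: needs > REFERENCE_BOX_MM extent in-plane
    pons_half = (
        math.ceil(REFERENCE_BOX_MM / (2 * vx)) + 1,
        math.ceil(REFERENCE_BOX_MM / (2 * vy)) + 1,
        max(1, math.ceil(REFERENCE_BOX_MM / (2 * vz))),
    )
    pons_center = (nx // 2, ny // 2, 1 + pons_half[2])
    pons_sl = _block(pons_center, pons_half)
    for sl, n in zip(pons_sl, grid_shape):
        if sl.start < 0 or sl.stop > n:
            raise ValueError(
                f"grid {grid_shape} at {voxel_size_mm} mm too small to host the "
                f"{REFERENCE_BOX_MM:g} mm pons reference box"
            )
    labels[pons_sl] = LABEL_CODES[PONS]

    # VOI cells above the pons: 2 z-slabs x 4 quadrants
    z_lo = pons_sl[2].stop + 1
    z_extent = nz - 1 - z_lo
    if z_extent < 6:
        raise ValueError(f"grid {grid_shape} too small to place VOI blocks above the pons")
    z_edges = [z_lo, z_lo + z_extent // 2, nz - 1]
    x_edges = [1, nx // 2, nx - 1]
    y_edges = [1, ny // 2, ny - 1]

    cells = []
    for zi in range(2):
        for yi in range(2):
            for xi in range(2):
                cells.append(
                    (
                        (x_edges[xi], x_edges[xi + 1]),
                        (y_edges[yi], y_edges[yi + 1]),
                        (z_edges[zi], z_edges[zi + 1]),
                    )
                )
    for name, cell in zip(VOI_NAMES, cells):
        sls = []
        for lo, hi in cell:
            span = hi - lo
            pad = max(1, span // 5)  # keep a background gap between blocks
            if span - 2 * pad < 2:
                raise ValueError(
                    f"grid {grid_shape} too small: VOI {name} block would have "
                    f"fewer than 2 voxels along one axis"
                )
            sls.append(slice(lo + pad, hi - pad))
        region = labels[tuple(sls)]
        if np.any(region != 0):
            raise ValueError("internal layout error: VOI block overlaps another region")
        labels[tuple(sls)] = LABEL_CODES[name]

    atlas = LabelAtlas(
        labels=labels,
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        affine=_ras_affine(voxel_size_mm),
        label_map={v: k for k, v in LABEL_CODES.items()},
    )
    counts = atlas.region_voxel_counts()
    empty = [n for n in REGION_NAMES if counts.get(n, 0) == 0]
    if empty:
        raise ValueError(f"grid {grid_shape} leaves regions empty: {empty}")
    return atlas


def render_pet_volume(
    subject_voi_suvr: dict[str, float],
    atlas: LabelAtlas,
    pons_activity: float = 1000.0,
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
    background_fraction: float = 0.25,
) -> PetVolume:
    """Render a phantom whose regional means invert the SUVr definition.

    Before noise, mean activity in VOI r is ``subject_voi_suvr[r] *
    pons_activity``, the pons is flat at ``pons_activity``, and background is
    ``background_fraction * pons_activity``. Voxel noise is multiplicative
    Gaussian with SD ``noise_sd_fraction`` of the local mean, clipped at 0.
    """
    if pons_activity <= 0:
        raise ValueError("pons_activity must be positive")
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be non-negative")
    missing = [v for v in atlas.voi_names() if v not in subject_voi_suvr]
    if missing:
        raise ValueError(f"no SUVr value supplied for VOIs: {missing}")

    img = np.full(atlas.shape, background_fraction * pons_activity, dtype=float)
    img[atlas.mask(PONS)] = pons_activity
    for voi in atlas.voi_names():
        img[atlas.mask(voi)] = subject_voi_suvr[voi] * pons_activity

    if noise_sd_fraction > 0:
        rng = np.random.default_rng(seed)
        img = img * (1.0 + rng.normal(0.0, noise_sd_fraction, atlas.shape))
        np.clip(img, 0.0, None, out=img)

    return PetVolume(img, atlas.voxel_size_mm, atlas.affine.copy())


# ---------------------------------------------------------------------------
# NIfTI-1 / JSON serialization

def save_volume(volume: PetVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), volume.affine), str(path))


def load_volume(path) -> PetVolume:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PetVolume(np.asarray(img.dataobj, dtype=float), voxel, img.affine)


def save_atlas(atlas: LabelAtlas, nifti_path, labelmap_path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(nifti_path))
    with open(labelmap_path, "w") as fh:
        json.dump({str(k): v for k, v in atlas.label_map.items()}, fh, indent=2)


def load_atlas(nifti_path, labelmap_path) -> LabelAtlas:
    img = nib.load(str(nifti_path))
    with open(labelmap_path) as fh:
        label_map = {int(k): v for k, v in json.load(fh).items()}
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelAtlas(np.asarray(img.dataobj).astype(np.int16), voxel, img.affine, label_map)
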