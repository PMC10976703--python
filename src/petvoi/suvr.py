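"""Pons-referenced SUVr computation and VOI aggregation.

The standard uptake value ratio divides every voxel by the mean activity of a
reference region spared by the disease — here the pons, either its whole
labeled extent or a mid-pons box (16 mm edge by default) centered at the pons
centroid and clipped to the pons mask. Per-VOI values are the arithmetic mean
of SUVr voxels inside each atlas region.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .phantom import PONS, LabelAtlas, PetVolume


class ReferenceMode(str, Enum):
    PONS_LABEL_MEAN = "label"
    PONS_CENTERED_BOX = "box"


@dataclass(frozen=True)
class ReferenceSpec:
    """How to form the reference mean: whole pons label, or a centered box."""

    mode: ReferenceMode = ReferenceMode.PONS_LABEL_MEAN
    box_edge_mm: float = 16.0

    def __post_init__(self) -> None:
        if self.box_edge_mm <= 0:
            raise ValueError("box_edge_mm must be positive")


@dataclass(frozen=True)
class SuvrVolume:
    """Voxelwise SUVr grid with its geometry and the reference mean used."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    reference_mean: float


def _reference_mask(atlas: LabelAtlas, spec: ReferenceSpec) -> np.ndarray:
    pons = atlas.mask(PONS)
    if not pons.any():
        raise ValueError("atlas has no pons voxels; cannot form a reference region")
    if spec.mode == ReferenceMode.PONS_LABEL_MEAN:
        return pons
    # box mode: cube of edge box_edge_mm centered at the pons centroid,
    # intersected with the pons mask
    centroid = np.array(np.nonzero(pons), dtype=float).mean(axis=1)
    half_vox = [spec.box_edge_mm / (2 * v) for v in atlas.voxel_size_mm]
    mask = np.zeros_like(pons)
    sls = tuple(
        slice(max(0, int(np.ceil(c - h))), min(n, int(np.floor(c + h)) + 1))
        for c, h, n in zip(centroid, half_vox, atlas.shape)
    )
    mask[sls] = True
    mask &= pons
    if not mask.any():
        raise ValueError("reference box clipped to the pons mask contains no voxels")
    return mask


def extract_reference_mean(
    volume: PetVolume, atlas: LabelAtlas, spec: ReferenceSpec | None = None
) -> float:
    """Mean activity over the reference voxels (must be strictly positive)."""
    spec = spec or ReferenceSpec()
    volume.check_compatible(atlas)
    mask = _reference_mask(atlas, spec)
    ref = float(volume.intensities[mask].mean())
    if ref <= 0:
        raise ValueError(f"reference mean must be positive, got {ref}")
    return ref


def compute_suvr_volume(volume: PetVolume, reference_mean: float) -> SuvrVolume:
    """Divide every voxel by the reference mean."""
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    return SuvrVolume(
        values=volume.intensities / reference_mean,
        voxel_size_mm=volume.voxel_size_mm,
        affine=volume.affine.copy(),
        reference_mean=float(reference_mean),
    )


def aggregate_vois(
    suvr_volume: SuvrVolume, atlas: LabelAtlas, subject_id: str = ""
) -> pd.DataFrame:
    """Mean SUVr per VOI; one row per named VOI in the atlas.

    Columns: subject_id, voi, mean_suvr, voxel_count.
    """
    if suvr_volume.values.shape != atlas.shape:
        raise ValueError("SUVr volume and atlas shapes differ")
    rows = []
    for voi in atlas.voi_names():
        mask = atlas.mask(voi)
        n = int(np.count_nonzero(mask))
        if n == 0:
            raise ValueError(f"VOI {voi!r} has no voxels in the atlas")
        rows.append(
            {
                "subject_id": subject_id,
                "voi": voi,
                "mean_suvr": float(suvr_volume.values[mask].mean()),
                "voxel_count": n,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "voi", "mean_suvr", "voxel_count"])


def measure_subject(
    volume: PetVolume,
    atlas: LabelAtlas,
    spec: ReferenceSpec | None = None,
    subject_id: str = "",
) -> pd.DataFrame:
    """Convenience: reference mean -> SUVr volume -> per-VOI means in one call."""
    ref = extract_reference_mean(volume, atlas, spec)
    return aggregate_vois(compute_suvr_volume(volume, ref), atlas, subject_id)
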