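"""Normative database construction and Z transformation.

A subject's regional SUVr is expressed in control-SD units:
``z = (subject - mean_controls) / SD_controls`` under the default orientation,
so that hypometabolism (low uptake) gives negative z and the clinical rule
"Z below -2" flags it. The opposite orientation (database - subject), as some
commercial reports print it, is available via ``Orientation.DB_MINUS_SUBJECT``
and is the exact negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .phantom import LabelAtlas
from .suvr import SuvrVolume

DEFAULT_SD_FLOOR = 1e-6


class Orientation(str, Enum):
    SUBJECT_MINUS_DB = "subject-db"
    DB_MINUS_SUBJECT = "db-subject"


@dataclass
class NormativeDB:
    """Per-VOI control mean/SD (and optionally voxelwise grids).

    ``table`` has one row per VOI with columns mu_db, sigma_db, n_controls.
    """

    table: pd.DataFrame
    sd_floor: float = DEFAULT_SD_FLOOR
    voxel_mu: np.ndarray | None = field(default=None, repr=False)
    voxel_sigma: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        required = {"voi", "mu_db", "sigma_db", "n_controls"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"normative table missing columns: {sorted(missing)}")
        if (self.table["sigma_db"] < self.sd_floor).any():
            raise ValueError("sigma_db below the configured floor")
        if (self.table["n_controls"] < 2).any():
            raise ValueError("normative entries need at least 2 controls")

    def lookup(self, voi: str) -> tuple[float, float]:
        row = self.table.loc[self.table["voi"] == voi]
        if row.empty:
            raise KeyError(f"VOI {voi!r} absent from the normative database")
        return float(row["mu_db"].iloc[0]), float(row["sigma_db"].iloc[0])

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    @classmethod
    def from_json(cls, path, sd_floor: float = DEFAULT_SD_FLOOR) -> "NormativeDB":
        return cls(pd.read_json(path, orient="records"), sd_floor=sd_floor)


def build_normative_db(
    control_measurements: pd.DataFrame, sd_floor: float = DEFAULT_SD_FLOOR
) -> NormativeDB:
    """Per-VOI sample mean and SD (n-1 denominator) over control subjects.

    ``control_measurements`` holds one row per (subject, VOI) with columns
    ``voi`` and ``mean_suvr``. Degenerate SDs are clamped up to ``sd_floor``.
    """
    if sd_floor <= 0:
        raise ValueError("sd_floor must be positive")
    rows = []
    for voi, grp in control_measurements.groupby("voi", sort=False):
        n = len(grp)
        if n < 2:
            raise ValueError(f"VOI {voi!r} has {n} control measurement(s); need at least 2")
        rows.append(
            {
                "voi": voi,
                "mu_db": float(grp["mean_suvr"].mean()),
                "sigma_db": max(float(grp["mean_suvr"].std(ddof=1)), sd_floor),
                "n_controls": n,
            }
        )
    if not rows:
        raise ValueError("no control measurements supplied")
    return NormativeDB(pd.DataFrame(rows), sd_floor=sd_floor)


def z_transform(
    measurements: pd.DataFrame,
    db: NormativeDB,
    orientation: Orientation = Orientation.SUBJECT_MINUS_DB,
) -> pd.DataFrame:
    """Z-score every (subject, VOI) measurement against the normative DB.

    Returns columns subject_id, voi, z. Default orientation gives negative z
    for hypometabolism; the other orientation negates every value.
    """
    zs = []
    for row in measurements.itertuples(index=False):
        mu, sigma = db.lookup(row.voi)
        z = (row.mean_suvr - mu) / sigma
        if orientation == Orientation.DB_MINUS_SUBJECT:
            z = -z
        zs.append({"subject_id": row.subject_id, "voi": row.voi, "z": float(z)})
    out = pd.DataFrame(zs, columns=["subject_id", "voi", "z"])
    if not np.isfinite(out["z"]).all():
        raise ValueError("non-finite z value produced; check the normative database")
    return out


def build_voxel_normative_db(
    control_volumes: list[SuvrVolume], sd_floor: float = DEFAULT_SD_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise control mean and SD grids from a stack of SUVr volumes."""
    if len(control_volumes) < 2:
        raise ValueError("need at least 2 control volumes for a voxelwise database")
    shapes = {v.values.shape for v in control_volumes}
    if len(shapes) != 1:
        raise ValueError("control volumes have mismatched shapes")
    stack = np.stack([v.values for v in control_volumes])
    mu = stack.mean(axis=0)
    sigma = np.maximum(stack.std(axis=0, ddof=1), sd_floor)
    return mu, sigma


def z_volume(
    suvr_volume: SuvrVolume,
    voxel_mu: np.ndarray,
    voxel_sigma: np.ndarray,
    orientation: Orientation = Orientation.SUBJECT_MINUS_DB,
) -> np.ndarray:
    """Voxelwise Z map under the same sign convention as ``z_transform``."""
    if suvr_volume.values.shape != voxel_mu.shape or voxel_mu.shape != voxel_sigma.shape:
        raise ValueError("SUVr volume and voxelwise mu/sigma grids have mismatched shapes")
    if np.any(voxel_sigma <= 0):
        raise ValueError("voxel sigma grid must be strictly positive")
    z = (suvr_volume.values - voxel_mu) / voxel_sigma
    if orientation == Orientation.DB_MINUS_SUBJECT:
        z = -z
    return z


def hypometabolic_mask(
    z_map: np.ndarray, threshold: float = -2.0, atlas: LabelAtlas | None = None
) -> np.ndarray:
    """Boolean mask of voxels with z strictly below the threshold.

    When an atlas is given, the mask is restricted to labeled (non-background)
    voxels, mirroring displays that show only brain regions with Z < -2.
    """
    mask = z_map < threshold
    if atlas is not None:
        mask &= atlas.labels != atlas.code_of("BACKGROUND")
    return mask
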