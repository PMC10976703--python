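"""End-to-end pipeline: simulate -> render -> SUVr -> normative Z -> classify
-> evaluate -> longitudinal trajectory.

Every run writes its effective configuration (JSON) next to the outputs and
stamps each table with the seed and a configuration hash, so reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import classify as cls
from . import cohort as coh
from . import longitudinal as lng
from . import phantom as phm
from . import suvr as suv
from . import zscore as zsc
from .defaults import DEFAULT_GROUP_SIZES, Z_THRESHOLD

log = logging.getLogger("petvoi")


class PipelineConfig(BaseModel):
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    group_sizes: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    profile_overrides: dict[str, tuple[float, float]] = Field(
        default_factory=dict,
        description="optional 'GROUP/VOI' -> (mean, sd) overrides of the SUVr profile",
    )
    severity_loading: float = 0.0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    pons_activity: float = 1000.0
    noise_sd_fraction: float = 0.05
    reference_mode: str = "label"  # "label" | "box"
    box_edge_mm: float = 16.0
    orientation: str = "subject-db"  # "subject-db" | "db-subject"
    threshold: float = Z_THRESHOLD
    prediction_rules: list[str] = Field(
        default_factory=lambda: ["MTL", "PCC", "MTL&PCC", "MTL|PCC"]
    )
    n_visits: int = 5
    output_dir: str = "petvoi_out"

    def config_hash(self) -> str:
        # hash the scientific configuration only, not where outputs land
        payload = self.model_dump(exclude={"output_dir"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:12]

    def regional_profile(self) -> coh.RegionalProfile:
        entries = dict(coh.RegionalProfile.default().entries)
        for key, (mean, sd) in self.profile_overrides.items():
            group, voi = key.split("/")
            entries[(group, voi)] = (float(mean), float(sd))
        return coh.RegionalProfile(entries)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and original context."""


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# petvoi run; seed={seed}; config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory tables and the output paths. Stage
    errors propagate as :class:`PipelineError` naming the failed stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    seed = config.seed
    bundle: dict = {"output_dir": str(out), "config_hash": cfg_hash}

    with open(out / "config.json", "w") as fh:
        json.dump(config.model_dump(), fh, indent=2, default=list)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
        return result

    def simulate():
        df = coh.generate_cohort(
            config.group_sizes, profile=config.regional_profile(), seed=seed,
            severity_loading=config.severity_loading,
        )
        df = coh.assign_conversion_times(df, seed=seed + 1)
        _write_tsv(df, out / "cohort.tsv", seed, cfg_hash)
        return df

    cohort_df = run_stage("simulate", simulate)

    def render_and_measure():
        atlas = phm.generate_atlas_phantom(config.grid_shape, config.voxel_size_mm)
        phm.save_atlas(atlas, out / "atlas.nii.gz", out / "atlas_labels.json")
        ref_spec = suv.ReferenceSpec(
            mode=suv.ReferenceMode(config.reference_mode), box_edge_mm=config.box_edge_mm
        )
        frames = []
        for i, row in enumerate(cohort_df.itertuples(index=False)):
            targets = {v: getattr(row, f"suvr_{v}") for v in atlas.voi_names()}
            vol = phm.render_pet_volume(
                targets, atlas, pons_activity=config.pons_activity,
                noise_sd_fraction=config.noise_sd_fraction, seed=seed + 1000 + i,
            )
            frames.append(suv.measure_subject(vol, atlas, ref_spec, row.subject_id))
        df = pd.concat(frames, ignore_index=True)
        _write_tsv(df, out / "voi_measurements.tsv", seed, cfg_hash)
        return df

    measurements = run_stage("render+suvr", render_and_measure)

    def build_db():
        controls = cohort_df.loc[cohort_df["group"] == "CN", "subject_id"]
        db = zsc.build_normative_db(measurements[measurements["subject_id"].isin(controls)])
        db.to_json(out / "normative_db.json")
        return db

    ndb = run_stage("normative", build_db)

    def z_scores():
        df = zsc.z_transform(measurements, ndb, zsc.Orientation(config.orientation))
        _write_tsv(df, out / "zscores.tsv", seed, cfg_hash)
        return df

    zscores = run_stage("zscore", z_scores)

    def classify_calls():
        df = cls.call_hypometabolism(zscores, threshold=config.threshold)
        _write_tsv(df, out / "hypometabolism_calls.tsv", seed, cfg_hash)
        prev = cls.hypometabolism_prevalence(df, cohort_df)
        _write_tsv(prev, out / "prevalence.tsv", seed, cfg_hash)
        return df

    calls = run_stage("classify", classify_calls)

    def evaluate():
        mci = cohort_df[cohort_df["group"].isin(["MCI_C", "MCI_NC"])]
        truth = (mci.set_index("subject_id")["group"] == "MCI_C").rename("converter")
        mci_calls = calls[calls["subject_id"].isin(mci["subject_id"])]
        report = {"seed": seed, "config": cfg_hash, "rules": {}}
        for expr in config.prediction_rules:
            pred = cls.predict_conversion(mci_calls, expr)
            table, diag = cls.evaluate_predictions(pred, truth)
            report["rules"][expr] = {
                "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
                "metrics": diag.as_dict(),
            }
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report

    metrics = run_stage("evaluate", evaluate)

    def trajectory():
        scores = coh.generate_longitudinal_scores(
            cohort_df, n_visits=config.n_visits, seed=seed + 2
        )
        _write_tsv(scores, out / "longitudinal_scores.tsv", seed, cfg_hash)
        fits = []
        for outcome in ("MMSE", "CASI"):
            res = lng.fit_marginal_trajectory(scores, cohort_df, outcome=outcome)
            fits.append(res.params.assign(outcome=outcome))
        fit_df = pd.concat(fits, ignore_index=True)
        _write_tsv(fit_df, out / "trajectory_fit.tsv", seed, cfg_hash)
        tests = [
            lng.visitwise_group_test(scores, "MCI_C", "MCI_NC", v, outcome).__dict__
            for outcome in ("MMSE", "CASI")
            for v in range(1, config.n_visits + 1)
        ]
        _write_tsv(pd.DataFrame(tests), out / "visit_tests.tsv", seed, cfg_hash)
        return scores, fit_df

    scores, fit_df = run_stage("trajectory", trajectory)

    bundle.update(
        cohort=cohort_df,
        measurements=measurements,
        normative_db=ndb,
        zscores=zscores,
        calls=calls,
        metrics=metrics,
        longitudinal_scores=scores,
        trajectory_fit=fit_df,
    )
    return bundle
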