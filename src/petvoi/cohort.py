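"""Synthetic longitudinal cohort generator.

Emulates a four-group memory-clinic cohort: per-subject regional FDG-PET SUVr
drawn from group profiles, demographics and baseline cognition, truncated-normal
conversion/observation intervals, and annual MMSE/CASI trajectories whose
group-by-visit drift follows the marginal-model coefficients in
:mod:`petvoi.defaults`.

Within-subject correlation of repeated scores is exchangeable; regional SUVr
values are independent across VOIs by default, with an optional common
"severity" factor that induces co-hypometabolism across regions and couples
low uptake to low baseline cognition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults
from .defaults import GROUPS, VOI_NAMES


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
    size: int = 1,
) -> np.ndarray:
    """Draw from Normal(mean, sd) conditioned on [low, high] by rejection.

    Exact (the accepted draws follow the truncated law); bounds in this
    package are always within a few SD of the mean so rejection is cheap.
    """
    if sd < 0:
        raise ValueError(f"negative SD {sd!r}")
    if sd == 0:
        out = np.full(size, mean)
        if np.any((out < low) | (out > high)):
            raise ValueError("degenerate distribution outside truncation bounds")
        return out
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


@dataclass(frozen=True)
class RegionalProfile:
    """Per-(group, VOI) SUVr mean and SD defining the generator's truth."""

    entries: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        for (group, voi), (mean, sd) in self.entries.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if voi not in VOI_NAMES:
                raise ValueError(f"unknown VOI {voi!r}")
            if mean <= 0:
                raise ValueError(f"non-positive SUVr mean for {(group, voi)}")
            if sd <= 0:
                raise ValueError(f"non-positive SUVr SD for {(group, voi)}")

    @classmethod
    def default(cls) -> "RegionalProfile":
        return cls(dict(defaults.REGIONAL_SUVR))

    def lookup(self, group: str, voi: str) -> tuple[float, float]:
        try:
            return self.entries[(group, voi)]
        except KeyError:
            raise KeyError(f"no SUVr profile entry for group {group!r}, VOI {voi!r}") from None

    def vois(self) -> tuple[str, ...]:
        return tuple(v for v in VOI_NAMES if any(k[1] == v for k in self.entries))


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of the longitudinal MMSE/CASI score generator.

    ``offsets[outcome][group][v-1]`` is the expected change from baseline at
    visit ``v`` (visit 1 is the reference, offset 0 for every group).
    ``covariates[outcome]`` holds the education (points/year) and male-sex
    (points) effects injected into baseline cognition. ``within_subject_corr``
    is the exchangeable correlation of repeated measurement noise.
    """

    offsets: dict[str, dict[str, tuple[float, ...]]] = field(
        default_factory=lambda: {
            "MMSE": {g: tuple(v) for g, v in defaults.TRAJECTORY_OFFSETS_MMSE.items()},
            "CASI": {g: tuple(v) for g, v in defaults.TRAJECTORY_OFFSETS_CASI.items()},
        }
    )
    covariates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.COVARIATE_EFFECTS.items()}
    )
    within_subject_corr: float = 0.5
    residual_sd: dict[str, float] = field(default_factory=lambda: {"MMSE": 2.0, "CASI": 6.0})

    def __post_init__(self) -> None:
        if not 0 <= self.within_subject_corr < 1:
            raise ValueError("within_subject_corr must lie in [0, 1)")
        for outcome, per_group in self.offsets.items():
            for group, offs in per_group.items():
                if offs and offs[0] != 0.0:
                    raise ValueError(
                        f"visit-1 offset must be 0 (reference level); got {offs[0]}"
                        f" for {outcome}/{group}"
                    )
        for sd in self.residual_sd.values():
            if sd < 0:
                raise ValueError("residual SD must be non-negative")

    @property
    def max_visits(self) -> int:
        return min(len(offs) for per_group in self.offsets.values() for offs in per_group.values())

    def with_zero_effects(self) -> "TrajectorySpec":
        """Copy with all offsets and covariate effects zeroed (null model)."""
        zero_offsets = {
            outcome: {g: tuple(0.0 for _ in offs) for g, offs in per_group.items()}
            for outcome, per_group in self.offsets.items()
        }
        zero_cov = {outcome: {k: 0.0 for k in cov} for outcome, cov in self.covariates.items()}
        return replace(self, offsets=zero_offsets, covariates=zero_cov)


def _baseline_scores(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    education: np.ndarray,
    edu_center: float,
    edu_sd: float,
    male: np.ndarray,
    male_fraction: float,
    beta_edu: float,
    beta_male: float,
    severity: np.ndarray,
    loading: float,
) -> np.ndarray:
    """Baseline cognition with centered demographic effects.

    The marginal group mean stays at ``mean`` because education and sex are
    centered at their configured group values; the idiosyncratic variance is
    reduced so the marginal SD stays close to ``sd``.
    """
    explained = beta_edu**2 * edu_sd**2 + beta_male**2 * male_fraction * (1 - male_fraction)
    resid_sd = math.sqrt(max(sd**2 - explained, (0.1 * sd) ** 2))
    eps = rng.normal(0.0, 1.0, n)
    noise = resid_sd * (loading * severity + math.sqrt(1 - loading**2) * eps)
    return (
        mean
        + beta_edu * (education - edu_center)
        + beta_male * (male.astype(float) - male_fraction)
        + noise
    )


def generate_cohort(
    group_sizes: dict[str, int],
    profile: RegionalProfile | None = None,
    seed: int = 0,
    trajectory: TrajectorySpec | None = None,
    severity_loading: float = 0.0,
) -> pd.DataFrame:
    """Generate the subject table with per-VOI "true" baseline SUVr values.

    Parameters
    ----------
    group_sizes
        Map diagnostic group -> number of subjects (missing groups mean 0).
    profile
        Per-(group, VOI) SUVr mean/SD; defaults to the published group table.
    seed
        Seed for the whole draw; identical seeds give identical tables.
    trajectory
        Source of the education/sex coefficients embedded in baseline
        cognition (defaults to the published marginal-model coefficients).
    severity_loading
        Loading in [0, 1) of a common per-subject severity factor shared by
        all regional SUVr draws and baseline cognition; 0 (default) makes
        regions independent given the group.

    Returns
    -------
    DataFrame with one row per subject: demographics, baseline MMSE/CASI,
    and ``suvr_<VOI>`` columns holding the subject's true regional SUVr.
    """
    if not 0 <= severity_loading < 1:
        raise ValueError("severity_loading must lie in [0, 1)")
    profile = profile or RegionalProfile.default()
    trajectory = trajectory or TrajectorySpec()
    for group, n in group_sizes.items():
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        if n < 0:
            raise ValueError(f"negative group size for {group!r}")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for group in GROUPS:
        n = int(group_sizes.get(group, 0))
        if n == 0:
            continue
        demo = defaults.DEMOGRAPHICS[group]
        age = _truncated_normal(rng, *demo["age"], low=0.0, size=n)
        education = _truncated_normal(rng, *demo["education"], low=0.0, size=n)
        # center covariates at the truncated draw's true mean so the marginal
        # cognition mean stays at the configured group value
        edu_center = truncated_normal_mean(*demo["education"], 0.0, np.inf)
        male = rng.random(n) < demo["male_fraction"]
        apoe4 = rng.random(n) < demo["apoe4_fraction"]
        severity = rng.normal(0.0, 1.0, n)  # shared "disease severity" factor

        lam = severity_loading
        mmse = _baseline_scores(
            rng, n, *demo["mmse"], education, edu_center, demo["education"][1],
            male, demo["male_fraction"],
            trajectory.covariates["MMSE"]["education_years"],
            trajectory.covariates["MMSE"]["male"],
            severity, lam,
        )
        casi = _baseline_scores(
            rng, n, *demo["casi"], education, edu_center, demo["education"][1],
            male, demo["male_fraction"],
            trajectory.covariates["CASI"]["education_years"],
            trajectory.covariates["CASI"]["male"],
            severity, lam,
        )
        mmse = np.clip(np.rint(mmse), 0, 30).astype(int)
        casi = np.clip(casi, 0.0, 100.0)

        suvr = {}
        for voi in profile.vois():
            mean, sd = profile.lookup(group, voi)
            eps = rng.normal(0.0, 1.0, n)
            vals = mean + sd * (lam * severity + math.sqrt(1 - lam**2) * eps)
            # truncate at 0: redraw the idiosyncratic part of invalid values
            bad = vals <= 0
            while np.any(bad):
                eps_new = rng.normal(0.0, 1.0, int(bad.sum()))
                vals[bad] = mean + sd * (
                    lam * severity[bad] + math.sqrt(1 - lam**2) * eps_new
                )
                bad = vals <= 0
            suvr[voi] = vals

        for i in range(n):
            row = {
                "subject_id": f"{group}_{i:03d}",
                "group": group,
                "age_years": age[i],
                "sex": "M" if male[i] else "F",
                "education_years": education[i],
                "apoe4_carrier": bool(apoe4[i]),
                "baseline_mmse": int(mmse[i]),
                "baseline_casi": float(casi[i]),
            }
            for voi in profile.vois():
                row[f"suvr_{voi}"] = float(suvr[voi][i])
            rows.append(row)

    columns = [
        "subject_id", "group", "age_years", "sex", "education_years",
        "apoe4_carrier", "baseline_mmse", "baseline_casi",
    ] + [f"suvr_{v}" for v in (profile.vois() if rows else VOI_NAMES)]
    return pd.DataFrame(rows, columns=columns)


def assign_conversion_times(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fill ``conversion_interval_years`` (converters) and ``followup_years``.

    Converter intervals follow a truncated Normal(3.70, 1.68) on [1, 8] years;
    non-converter observation time a truncated Normal(4.34, 1.26) on [2, 7].
    Controls and AD patients get their group clinical follow-up distribution,
    truncated at 0; a converter's follow-up never precedes its conversion.
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort must have a 'group' column")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["conversion_interval_years"] = np.nan
    out["followup_years"] = np.nan

    for group in GROUPS:
        idx = out.index[out["group"] == group]
        n = len(idx)
        if n == 0:
            continue
        if group == "MCI_C":
            ci = defaults.CONVERSION_INTERVAL
            conv = _truncated_normal(rng, ci["mean"], ci["sd"], ci["low"], ci["high"], n)
            out.loc[idx, "conversion_interval_years"] = conv
            fu_mean, fu_sd = defaults.DEMOGRAPHICS[group]["followup"]
            fu = _truncated_normal(rng, fu_mean, fu_sd, low=0.0, size=n)
            out.loc[idx, "followup_years"] = np.maximum(fu, conv)
        elif group == "MCI_NC":
            nc = defaults.NONCONVERTER_FOLLOWUP
            out.loc[idx, "followup_years"] = _truncated_normal(
                rng, nc["mean"], nc["sd"], nc["low"], nc["high"], n
            )
        else:
            fu_mean, fu_sd = defaults.DEMOGRAPHICS[group]["followup"]
            out.loc[idx, "followup_years"] = _truncated_normal(rng, fu_mean, fu_sd, 0.0, size=n)
    return out


def draw_conversion_intervals(n: int, seed: int = 0) -> np.ndarray:
    """Draw n converter conversion intervals from the default truncated model."""
    ci = defaults.CONVERSION_INTERVAL
    rng = np.random.default_rng(seed)
    return _truncated_normal(rng, ci["mean"], ci["sd"], ci["low"], ci["high"], n)


def draw_nonconverter_followups(n: int, seed: int = 0) -> np.ndarray:
    """Draw n non-converter observation times from the default truncated model."""
    nc = defaults.NONCONVERTER_FOLLOWUP
    rng = np.random.default_rng(seed)
    return _truncated_normal(rng, nc["mean"], nc["sd"], nc["low"], nc["high"], n)


def truncated_normal_mean(mean: float, sd: float, low: float, high: float) -> float:
    """Mean of a truncated normal, for comparing simulated interval draws."""
    from scipy import stats

    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def generate_longitudinal_scores(
    cohort: pd.DataFrame,
    spec: TrajectorySpec | None = None,
    n_visits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate annual MMSE/CASI measurements for every cohort subject.

    Visit 1 reproduces the subject's baseline scores exactly; visit v >= 2 is
    baseline + group offset(v) + exchangeable within-subject noise. MMSE is
    rounded to an integer and clipped to [0, 30], CASI clipped to [0, 100].
    The ``demented`` flag marks rows with MMSE below the dementia cut-off (20).
    """
    spec = spec or TrajectorySpec()
    if n_visits < 2:
        raise ValueError("n_visits must be at least 2")
    if n_visits > spec.max_visits:
        raise ValueError(
            f"n_visits={n_visits} exceeds the {spec.max_visits} configured visit offsets; "
            "no extrapolation rule is defined"
        )
    required = {"subject_id", "group", "baseline_mmse", "baseline_casi"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    rho = spec.within_subject_corr
    records: list[dict] = []
    for row in cohort.itertuples(index=False):
        base = {"MMSE": float(row.baseline_mmse), "CASI": float(row.baseline_casi)}
        noise: dict[str, np.ndarray] = {}
        for outcome in ("MMSE", "CASI"):
            u = rng.normal()  # subject-level component -> exchangeable structure
            e = rng.normal(size=n_visits - 1)
            noise[outcome] = spec.residual_sd[outcome] * (
                math.sqrt(rho) * u + math.sqrt(1 - rho) * e
            )
        for v in range(1, n_visits + 1):
            vals = {}
            for outcome in ("MMSE", "CASI"):
                if v == 1:
                    score = base[outcome]
                else:
                    offs = spec.offsets[outcome][row.group]
                    score = base[outcome] + offs[v - 1] + noise[outcome][v - 2]
                vals[outcome] = score
            mmse = int(np.clip(round(vals["MMSE"]), 0, 30))
            casi = float(np.clip(vals["CASI"], 0.0, 100.0))
            records.append(
                {
                    "subject_id": row.subject_id,
                    "group": row.group,
                    "visit_number": v,
                    "years_from_baseline": float(v - 1),
                    "mmse": mmse,
                    "casi": casi,
                    "demented": mmse < defaults.DEMENTIA_MMSE_THRESHOLD,
                }
            )
    return pd.DataFrame.from_records(records)


def converted_by_visit(scores: pd.DataFrame) -> pd.DataFrame:
    """Per subject and visit, whether MMSE has fallen below 20 at any visit so far."""
    out = scores.sort_values(["subject_id", "visit_number"]).copy()
    out["converted"] = out.groupby("subject_id")["demented"].cummax()
    return out


def write_table_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a table as TSV with a comment header recording the seed."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# petvoi table; seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
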