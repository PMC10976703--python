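"""Hypometabolism calls and conversion-prediction evaluation.

A VOI is called hypometabolic when its z is strictly below the threshold
(default -2). Conversion-prediction rules are boolean expressions over VOI
calls — a single VOI, a conjunction ("MTL&PCC") or a disjunction ("MTL|PCC")
— evaluated per subject and scored against the observed converter labels with
exact (Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import Z_THRESHOLD


def call_hypometabolism(z_records: pd.DataFrame, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Binary hypometabolism call per (subject, VOI): strictly z < threshold.

    Returns columns subject_id, voi, z, is_hypometabolic, threshold. A value
    exactly at the threshold is *not* flagged.
    """
    if not np.isfinite(z_records["z"]).all():
        raise ValueError("z records contain non-finite values")
    out = z_records[["subject_id", "voi", "z"]].copy()
    out["is_hypometabolic"] = out["z"] < threshold
    out["threshold"] = threshold
    return out


@dataclass(frozen=True)
class PredictionRule:
    """Single-VOI, all-of (conjunction), or any-of (disjunction) rule."""

    vois: tuple[str, ...]
    op: str = "single"  # "single" | "and" | "or"

    def __post_init__(self) -> None:
        if self.op not in ("single", "and", "or"):
            raise ValueError(f"unknown rule op {self.op!r}")
        if self.op == "single" and len(self.vois) != 1:
            raise ValueError("a single-VOI rule takes exactly one VOI")
        if self.op in ("and", "or") and len(self.vois) < 2:
            raise ValueError(f"an {self.op!r} rule takes at least two VOIs")

    @classmethod
    def parse(cls, expression: str) -> "PredictionRule":
        """Parse "MTL", "MTL&PCC" or "MTL|PCC" (no mixed operators)."""
        expr = expression.replace(" ", "")
        if "&" in expr and "|" in expr:
            raise ValueError(f"mixed &/| not supported in rule {expression!r}")
        if "&" in expr:
            return cls(tuple(expr.split("&")), "and")
        if "|" in expr:
            return cls(tuple(expr.split("|")), "or")
        return cls((expr,), "single")

    def __str__(self) -> str:
        sep = {"single": "", "and": "&", "or": "|"}[self.op]
        return sep.join(self.vois)

    def evaluate(self, calls: dict[str, bool]) -> bool:
        try:
            values = [calls[v] for v in self.vois]
        except KeyError as exc:
            raise KeyError(f"rule references VOI {exc.args[0]!r} with no call") from None
        if self.op == "and":
            return all(values)
        if self.op == "or":
            return any(values)
        return values[0]


def predict_conversion(calls: pd.DataFrame, rule: PredictionRule | str) -> pd.Series:
    """Per-subject boolean prediction by evaluating the rule on VOI calls."""
    if isinstance(rule, str):
        rule = PredictionRule.parse(rule)
    wide = calls.pivot(index="subject_id", columns="voi", values="is_hypometabolic")
    missing = [v for v in rule.vois if v not in wide.columns]
    if missing:
        raise KeyError(f"calls table lacks VOIs {missing} required by rule {rule}")
    sub = wide[list(rule.vois)]
    if sub.isna().any().any():
        raise ValueError("some subjects lack calls for the rule's VOIs")
    if rule.op == "and":
        pred = sub.all(axis=1)
    elif rule.op == "or":
        pred = sub.any(axis=1)
    else:
        pred = sub.iloc[:, 0]
    return pred.astype(bool).rename("predicted_converter")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) two-sided confidence interval."""
    if n == 0:
        raise ValueError("cannot form a CI with n = 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy with exact binomial 95% CIs.

    A metric whose denominator is zero is reported as None (absent), never
    coerced to 0; its CI is None as well.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    ci: dict[str, tuple[float, float] | None]

    def as_dict(self) -> dict:
        return {
            name: {
                "value": getattr(self, name),
                "ci95": list(self.ci[name]) if self.ci[name] is not None else None,
            }
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        }


def _ratio(k: int, n: int, name: str) -> tuple[float | None, tuple[float, float] | None]:
    if n == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent")
        return None, None
    return k / n, clopper_pearson(k, n)


def evaluate_predictions(
    predictions: pd.Series, truth_labels: pd.Series
) -> tuple[ConfusionTable, DiagnosticMetrics]:
    """Cross-tabulate boolean predictions against observed conversion labels.

    Both inputs are indexed by subject_id; the subject sets must match.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    if set(predictions.index) != set(truth_labels.index):
        raise ValueError("prediction and truth subject sets differ")
    truth = truth_labels.reindex(predictions.index).astype(bool)
    pred = predictions.astype(bool)

    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)

    sens, ci_sens = _ratio(tp, tp + fn, "sensitivity")
    spec, ci_spec = _ratio(tn, tn + fp, "specificity")
    ppv, ci_ppv = _ratio(tp, tp + fp, "ppv")
    npv, ci_npv = _ratio(tn, tn + fn, "npv")
    acc, ci_acc = _ratio(tp + tn, table.total, "accuracy")
    metrics = DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        ci={
            "sensitivity": ci_sens,
            "specificity": ci_spec,
            "ppv": ci_ppv,
            "npv": ci_npv,
            "accuracy": ci_acc,
        },
    )
    return table, metrics


def hypometabolism_prevalence(calls: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Fraction of subjects flagged hypometabolic, per diagnostic group and VOI.

    Returns columns group, voi, n_hypometabolic, n_subjects, fraction.
    """
    merged = calls.merge(cohort[["subject_id", "group"]], on="subject_id", how="left")
    if merged["group"].isna().any():
        raise ValueError("some calls reference subjects absent from the cohort")
    rows = []
    for (group, voi), grp in merged.groupby(["group", "voi"], sort=False):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty group {group!r} for VOI {voi!r}")
        k = int(grp["is_hypometabolic"].sum())
        rows.append(
            {"group": group, "voi": voi, "n_hypometabolic": k, "n_subjects": n,
             "fraction": k / n}
        )
    return pd.DataFrame(rows, columns=["group", "voi", "n_hypometabolic", "n_subjects", "fraction"])
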