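"""Longitudinal and nonparametric statistics for cognitive trajectories.

Covers the marginal (GEE) trajectory model for MMSE/CASI with exchangeable
working correlation and robust standard errors, visit-wise Mann-Whitney group
comparisons, paired two-scan Wilcoxon signed-rank tests per VOI, and Spearman
correlations between regional Z scores and cognition.

Estimation of the marginal model is delegated to statsmodels; this module owns
the term coding (control group and visit 1 as reference levels, measurement
number categorical) and the tidy output contract. Rank tests use exact null
distributions for small samples (n <= 10, no ties) and tie-corrected normal
approximations otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_MAX = 10  # largest sample size for exact rank-test null enumeration


def _exact_signed_rank_p(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided signed-rank p by enumerating all 2^n sign patterns.

    Handles tied absolute differences with average ranks, which scipy's exact
    mode does not; zeros must already be removed. Returns (W+, p).
    """
    import itertools

    ranks = stats.rankdata(np.abs(diff))
    w_plus = float(ranks[diff > 0].sum())
    mean_w = ranks.sum() / 2
    n = len(diff)
    count = 0
    for signs in itertools.product((False, True), repeat=n):
        w = ranks[np.array(signs)].sum()
        if abs(w - mean_w) >= abs(w_plus - mean_w) - 1e-12:
            count += 1
    return w_plus, count / 2**n


@dataclass(frozen=True)
class TrajectoryModelResult:
    """Tidy GEE fit: one row per term with estimate, robust SE, and p."""

    params: pd.DataFrame  # columns: term, estimate, robust_se, p_value
    cov_struct: str
    outcome: str
    n_subjects: int
    n_observations: int

    def term(self, name_fragment: str) -> pd.Series:
        """Return the unique parameter row whose term contains the fragment."""
        hits = self.params[self.params["term"].str.contains(name_fragment, regex=False)]
        if len(hits) != 1:
            raise KeyError(
                f"{len(hits)} terms match {name_fragment!r}: {list(hits['term'])}"
            )
        return hits.iloc[0]


def _prepare_model_frame(
    long_scores: pd.DataFrame, cohort: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    outcome = outcome.upper()
    if outcome not in ("MMSE", "CASI"):
        raise ValueError("outcome must be 'MMSE' or 'CASI'")
    cols = ["subject_id", "sex", "education_years", "age_years"]
    df = long_scores.merge(cohort[cols], on="subject_id", how="left", validate="m:1")
    if df["sex"].isna().any():
        raise ValueError("longitudinal scores reference subjects absent from the cohort")
    df["male"] = (df["sex"] == "M").astype(float)
    df["y"] = df["mmse" if outcome == "MMSE" else "casi"].astype(float)
    if df["y"].isna().all():
        raise ValueError("outcome is entirely missing")
    return df


def fit_marginal_trajectory(
    long_scores: pd.DataFrame,
    cohort: pd.DataFrame,
    outcome: str = "MMSE",
    terms: str | None = None,
) -> TrajectoryModelResult:
    """Fit the marginal trajectory model with exchangeable working correlation.

    The default design is ``male + education_years + group x visit`` with the
    control group and visit 1 as reference levels and measurement number
    treated as categorical. ``terms`` may override the right-hand side with
    any patsy formula over the merged score/cohort frame.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _prepare_model_frame(long_scores, cohort, outcome)
    if df.groupby("subject_id")["visit_number"].nunique().min() < 2:
        raise ValueError("every included subject needs at least 2 visits")
    rhs = terms or (
        "male + education_years + C(group, Treatment('CN')) * C(visit_number)"
    )
    model = smf.gee(
        f"y ~ {rhs}",
        groups="subject_id",
        data=df,
        cov_struct=sm.cov_struct.Exchangeable(),
        family=sm.families.Gaussian(),
    )
    fit = model.fit()  # robust (sandwich) covariance is the statsmodels default
    params = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.values,
            "robust_se": fit.bse.values,
            "p_value": fit.pvalues.values,
        }
    )
    if not np.isfinite(params["estimate"]).all():
        raise ValueError("singular design: non-finite coefficient estimates")
    return TrajectoryModelResult(
        params=params,
        cov_struct="exchangeable",
        outcome=outcome.upper(),
        n_subjects=df["subject_id"].nunique(),
        n_observations=len(df),
    )


@dataclass(frozen=True)
class VisitComparison:
    visit_number: int
    group_a: str
    group_b: str
    outcome: str
    statistic: float
    p_value: float
    method: str


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p by enumerating all group assignments.

    Average ranks handle ties, which scipy's exact mode rejects.
    Returns (U of sample a, p).
    """
    import itertools

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    mean_u = n_a * (n - n_a) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def _rank_method(a: np.ndarray, b: np.ndarray) -> str:
    if max(len(a), len(b)) > EXACT_N_MAX:
        return "asymptotic"
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    return "exact" if no_ties else "exact-ties"


def visitwise_group_test(
    long_scores: pd.DataFrame,
    group_a: str,
    group_b: str,
    visit: int,
    outcome: str = "MMSE",
) -> VisitComparison:
    """Two-sided Mann-Whitney rank-sum comparison of two groups at one visit."""
    col = outcome.lower()
    if col not in ("mmse", "casi"):
        raise ValueError("outcome must be 'MMSE' or 'CASI'")
    at_visit = long_scores[long_scores["visit_number"] == visit]
    a = at_visit.loc[at_visit["group"] == group_a, col].to_numpy(dtype=float)
    b = at_visit.loc[at_visit["group"] == group_b, col].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"group empty at visit {visit}: n_a={len(a)}, n_b={len(b)}")
    method = _rank_method(a, b)
    if method == "exact-ties":
        statistic, p_value = _exact_rank_sum_p(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return VisitComparison(
        visit_number=visit,
        group_a=group_a,
        group_b=group_b,
        outcome=outcome.upper(),
        statistic=statistic,
        p_value=p_value,
        method=method,
    )


def first_significant_visit(
    long_scores: pd.DataFrame,
    group_a: str,
    group_b: str,
    outcome: str = "MMSE",
    alpha: float = 0.05,
) -> int | None:
    """Scan visits in order; return the first with p < alpha, else None."""
    visits = sorted(long_scores["visit_number"].unique())
    for v in visits:
        cmp = visitwise_group_test(long_scores, group_a, group_b, v, outcome)
        if cmp.p_value < alpha:
            return int(v)
    return None


def paired_scan_test(z_baseline: pd.DataFrame, z_followup: pd.DataFrame) -> pd.DataFrame:
    """Per-VOI two-sided Wilcoxon signed-rank test between two scans.

    Inputs carry columns subject_id, voi, z; subjects are paired by id within
    each VOI. When every paired difference is zero there is no evidence either
    way and p is reported as 1.0 with a NaN statistic (documented convention).
    Returns columns voi, n_pairs, statistic, p_value, method.
    """
    merged = z_baseline.merge(
        z_followup, on=["subject_id", "voi"], suffixes=("_base", "_follow")
    )
    if merged.empty:
        raise ValueError("no complete subject pairs shared by the two scans")
    rows = []
    for voi, grp in merged.groupby("voi", sort=False):
        diff = (grp["z_follow"] - grp["z_base"]).to_numpy(dtype=float)
        n = len(diff)
        if np.all(diff == 0):
            rows.append(
                {"voi": voi, "n_pairs": n, "statistic": np.nan, "p_value": 1.0,
                 "method": "all-zero"}
            )
            continue
        nonzero = diff[diff != 0]
        if len(nonzero) <= EXACT_N_MAX:
            # enumerate the exact null; unlike scipy's exact mode this also
            # covers tied absolute differences (zeros dropped first)
            stat, p = _exact_signed_rank_p(nonzero)
            rows.append({"voi": voi, "n_pairs": n, "statistic": stat,
                         "p_value": p, "method": "exact"})
        else:
            res = stats.wilcoxon(diff, alternative="two-sided", method="approx")
            rows.append({"voi": voi, "n_pairs": n, "statistic": float(res.statistic),
                         "p_value": float(res.pvalue), "method": "approx"})
    return pd.DataFrame(rows, columns=["voi", "n_pairs", "statistic", "p_value", "method"])


def correlate_z_cognition(
    z_records: pd.DataFrame,
    cohort: pd.DataFrame,
    score_column: str = "baseline_mmse",
) -> pd.DataFrame:
    """Spearman rank correlation between regional Z and cognition, per group/VOI.

    Tie handling uses average ranks (scipy's convention). Requires at least 3
    paired observations per cell; a constant input vector is an error.
    Returns columns group, voi, n, rho, p_value.
    """
    merged = z_records.merge(
        cohort[["subject_id", "group", score_column]], on="subject_id", validate="m:1"
    )
    rows = []
    for (group, voi), grp in merged.groupby(["group", "voi"], sort=False):
        z = grp["z"].to_numpy(dtype=float)
        s = grp[score_column].to_numpy(dtype=float)
        if len(z) < 3:
            raise ValueError(f"fewer than 3 paired observations for {group}/{voi}")
        if np.all(z == z[0]) or np.all(s == s[0]):
            raise ValueError(f"constant input vector for {group}/{voi}")
        rho, p = stats.spearmanr(z, s)
        rows.append({"group": group, "voi": voi, "n": len(z), "rho": float(rho),
                     "p_value": float(p)})
    return pd.DataFrame(rows, columns=["group", "voi", "n", "rho", "p_value"])
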