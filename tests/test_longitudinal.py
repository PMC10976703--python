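"""Marginal trajectory model, rank tests, and Z-cognition correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import petvoi as pv
from petvoi.defaults import VOI_NAMES

from conftest import PRINTED_SIZES


def exact_mannwhitney_p(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_stat(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    observed = u_stat(range(n_a))
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        if abs(u_stat(idx) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


def exact_wilcoxon_p(diffs):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = ranks[d > 0].sum()
    n = len(d)
    mean_w = ranks.sum() / 2
    count = total = 0
    for signs in itertools.product([0, 1], repeat=n):
        total += 1
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean_w) >= abs(w_plus - mean_w) - 1e-12:
            count += 1
    return count / total


class TestMarginalModel:
    def test_null_generator_gives_null_interactions(self):
        """Zero offsets and covariate effects on a mid-scale cohort (identical
        baseline distributions, far from the instrument bounds) leave every
        group-by-visit interaction within 3 robust SE of zero."""
        rng = np.random.default_rng(0)
        n = 40
        rows = []
        for group in PRINTED_SIZES:
            for i in range(n):
                rows.append({
                    "subject_id": f"{group}_{i}", "group": group,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "education_years": float(rng.uniform(3, 16)),
                    "age_years": float(rng.uniform(60, 85)),
                    "baseline_mmse": int(rng.integers(14, 22)),
                    "baseline_casi": float(rng.uniform(40, 70)),
                })
        null_cohort = pd.DataFrame(rows)
        spec = pv.TrajectorySpec().with_zero_effects()
        scores = pv.generate_longitudinal_scores(null_cohort, spec, n_visits=5, seed=0)
        res = pv.fit_marginal_trajectory(scores, null_cohort, "MMSE")
        inter = res.params[res.params["term"].str.contains(":")]
        assert len(inter) == 3 * 4  # 3 non-reference groups x 4 non-reference visits
        assert (inter["estimate"].abs() < 3 * inter["robust_se"]).all()

    def test_output_contract(self, printed_cohort):
        scores = pv.generate_longitudinal_scores(printed_cohort, n_visits=3, seed=0)
        res = pv.fit_marginal_trajectory(scores, printed_cohort, "CASI")
        assert res.cov_struct == "exchangeable"
        assert res.outcome == "CASI"
        assert res.n_subjects == len(printed_cohort)
        assert res.n_observations == 3 * len(printed_cohort)
        assert set(res.params.columns) == {"term", "estimate", "robust_se", "p_value"}
        assert np.isfinite(res.params["estimate"]).all()

    def test_single_visit_subjects_rejected(self, printed_cohort):
        scores = pv.generate_longitudinal_scores(printed_cohort, n_visits=2, seed=0)
        only_first = scores[scores["visit_number"] == 1]
        with pytest.raises(ValueError, match="2 visits"):
            pv.fit_marginal_trajectory(only_first, printed_cohort, "MMSE")


class TestVisitwiseComparison:
    def score_frame(self, a, b, visit=1):
        rows = [
            {"subject_id": f"a{i}", "group": "MCI_C", "visit_number": visit, "mmse": v,
             "casi": float(v)}
            for i, v in enumerate(a)
        ] + [
            {"subject_id": f"b{i}", "group": "MCI_NC", "visit_number": visit, "mmse": v,
             "casi": float(v)}
            for i, v in enumerate(b)
        ]
        return pd.DataFrame(rows)

    def test_identical_samples_not_significant(self):
        scores = self.score_frame([20, 21, 22, 23], [20, 21, 22, 23])
        cmp = pv.visitwise_group_test(scores, "MCI_C", "MCI_NC", 1)
        assert cmp.p_value >= 0.99

    def test_fully_separated_samples_match_exact_enumeration(self):
        a, b = [1, 2, 3], [10, 11, 12]
        scores = self.score_frame(a, b)
        cmp = pv.visitwise_group_test(scores, "MCI_C", "MCI_NC", 1)
        assert cmp.statistic == 0.0
        assert cmp.method == "exact"
        assert cmp.p_value == pytest.approx(exact_mannwhitney_p(a, b))
        assert cmp.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("a,b", [([3, 9, 4, 7], [5, 12, 8]), ([1, 6, 2], [4, 10, 11, 13])])
    def test_small_sample_p_equals_enumeration_oracle(self, a, b):
        cmp = pv.visitwise_group_test(self.score_frame(a, b), "MCI_C", "MCI_NC", 1)
        assert cmp.p_value == pytest.approx(exact_mannwhitney_p(a, b))

    @pytest.mark.parametrize("transform", [lambda x: x**3, lambda x: 5 * x + 2, math.exp])
    def test_invariance_under_monotone_transform(self, transform):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 12)
        base = pv.visitwise_group_test(self.score_frame(a, b), "MCI_C", "MCI_NC", 1, "CASI")
        ta = [transform(x) for x in a]
        tb = [transform(x) for x in b]
        trans = pv.visitwise_group_test(self.score_frame(ta, tb), "MCI_C", "MCI_NC", 1, "CASI")
        assert trans.p_value == pytest.approx(base.p_value)

    def test_empty_group_at_visit_rejected(self):
        scores = self.score_frame([1, 2], [])
        with pytest.raises(ValueError, match="empty"):
            pv.visitwise_group_test(scores, "MCI_C", "MCI_NC", 1)

    def test_converter_separation_grows_by_visit_three(self):
        """At published sample sizes, visit 3 separates the MCI groups far more
        reliably than baseline, where the difference is borderline."""
        sig3 = p3_below_p1 = 0
        reps = 25
        for s in range(reps):
            cohort = pv.generate_cohort({"MCI_C": 44, "MCI_NC": 38}, seed=s)
            scores = pv.generate_longitudinal_scores(cohort, n_visits=3, seed=s)
            p1 = pv.visitwise_group_test(scores, "MCI_C", "MCI_NC", 1, "MMSE").p_value
            p3 = pv.visitwise_group_test(scores, "MCI_C", "MCI_NC", 3, "MMSE").p_value
            sig3 += p3 < 0.05
            p3_below_p1 += p3 < p1
        assert sig3 >= 0.8 * reps
        assert p3_below_p1 >= 0.8 * reps

    def test_first_significant_visit_scan(self):
        # groups constructed to separate only from visit 2 onwards
        rows = []
        for v, (mu_a, mu_b) in enumerate([(20, 20), (25, 10)], start=1):
            rng = np.random.default_rng(v)
            for i in range(12):
                rows.append({"subject_id": f"a{i}", "group": "MCI_C", "visit_number": v,
                             "mmse": mu_a + rng.integers(-2, 3), "casi": 0.0})
                rows.append({"subject_id": f"b{i}", "group": "MCI_NC", "visit_number": v,
                             "mmse": mu_b + rng.integers(-2, 3), "casi": 0.0})
        first = pv.first_significant_visit(pd.DataFrame(rows), "MCI_C", "MCI_NC", "MMSE")
        assert first == 2


class TestPairedScans:
    def z_frames(self, deltas, n=8, voi="MTL"):
        rng = np.random.default_rng(9)
        base = rng.normal(-1, 0.8, n)
        zb = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "voi": voi, "z": base})
        zf = zb.copy()
        zf["z"] = base + deltas
        return zb, zf

    def test_identical_scans_report_p_one(self):
        zb, zf = self.z_frames(0.0)
        out = pv.paired_scan_test(zb, zf)
        assert out["p_value"].iloc[0] == 1.0
        assert out["method"].iloc[0] == "all-zero"

    def test_uniform_decline_matches_sign_flip_enumeration(self):
        zb, zf = self.z_frames(-1.0, n=8)
        out = pv.paired_scan_test(zb, zf)
        diffs = (zf["z"] - zb["z"]).to_numpy()
        assert out["p_value"].iloc[0] == pytest.approx(exact_wilcoxon_p(diffs))
        assert out["p_value"].iloc[0] == pytest.approx(2 / 2**8)

    def test_mixed_differences_match_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        deltas = rng.normal(-0.6, 0.5, 9)
        zb, zf = self.z_frames(deltas, n=9)
        out = pv.paired_scan_test(zb, zf)
        assert out["p_value"].iloc[0] == pytest.approx(
            exact_wilcoxon_p((zf["z"] - zb["z"]).to_numpy())
        )

    def test_no_shared_pairs_rejected(self):
        zb = pd.DataFrame({"subject_id": ["a"], "voi": ["MTL"], "z": [0.0]})
        zf = pd.DataFrame({"subject_id": ["b"], "voi": ["MTL"], "z": [0.0]})
        with pytest.raises(ValueError, match="pairs"):
            pv.paired_scan_test(zb, zf)

    def test_converter_decline_detected_in_most_vois(self):
        """24 converter pairs with a configured decline of ~0.75 control-SD in
        every VOI should reach significance in nearly all regions."""
        rng = np.random.default_rng(10)
        n = 24
        rows_b, rows_f = [], []
        for voi in VOI_NAMES:
            base = rng.normal(-1.0, 1.0, n)
            follow = base - 0.75 + rng.normal(0, 0.5, n)
            for i in range(n):
                rows_b.append({"subject_id": f"s{i}", "voi": voi, "z": base[i]})
                rows_f.append({"subject_id": f"s{i}", "voi": voi, "z": follow[i]})
        out = pv.paired_scan_test(pd.DataFrame(rows_b), pd.DataFrame(rows_f))
        assert (out["p_value"] < 0.05).sum() >= 6


class TestZCognitionCorrelation:
    def cohort_frame(self, scores, group="AD"):
        return pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(len(scores))], "group": group,
             "baseline_mmse": scores}
        )

    def z_frame(self, zs, voi="PCC"):
        return pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(len(zs))], "voi": voi, "z": zs}
        )

    def test_perfect_monotone_association(self):
        out = pv.correlate_z_cognition(
            self.z_frame([-3.0, -2.0, -1.0, 0.0]), self.cohort_frame([10, 15, 20, 25])
        )
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        # pairs (1,2),(2,1),(3,3): rank differences give rho = 1 - 6*2/24 = 0.5
        out = pv.correlate_z_cognition(
            self.z_frame([1.0, 2.0, 3.0]), self.cohort_frame([2, 1, 3])
        )
        assert out["rho"].iloc[0] == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pv.correlate_z_cognition(
                self.z_frame([1.0, 1.0, 1.0]), self.cohort_frame([1, 2, 3])
            )

    def test_severity_factor_links_pcc_z_to_mmse_in_ad(self):
        """With a common severity factor the generator couples low regional
        SUVr (hence low Z) to low baseline MMSE within the AD group."""
        cohort = pv.generate_cohort({"AD": 300, "CN": 60}, seed=11, severity_loading=0.7)
        meas = pd.DataFrame(
            [
                {"subject_id": r.subject_id, "voi": "PCC", "mean_suvr": r.suvr_PCC,
                 "voxel_count": 1}
                for r in cohort.itertuples()
            ]
        )
        controls = meas[meas["subject_id"].str.startswith("CN")]
        db = pv.build_normative_db(controls)
        z = pv.z_transform(meas, db)
        out = pv.correlate_z_cognition(z, cohort)
        ad = out[(out["group"] == "AD") & (out["voi"] == "PCC")].iloc[0]
        assert ad["rho"] > 0.2
        assert ad["p_value"] < 0.05
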