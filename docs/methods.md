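# Methods

This note documents the models, generator design, numerical choices and known
limitations of petvoi. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Imaging model

**Geometry.** All volumes live on a regular grid with an RAS+ affine and
0-based voxel indices; a PET volume and its atlas must share shape and affine
exactly (checked on every pairing). Voxels on region boundaries belong to the
label stored in the atlas — there is no partial-volume weighting.

**Atlas phantom.** `generate_atlas_phantom` lays out nine mutually exclusive
regions deterministically: seven cortical VOI blocks (frontal, parietal,
medial temporal, lateral temporal, posterior cingulate, precuneus, occipital)
occupying the central portions of eight cells (two z-slabs by four in-plane
quadrants, one cell left as background), and a pons block placed low and
medial with in-plane extent strictly greater than the 16 mm reference box.
Construction fails with a diagnostic if the grid cannot host every region at
the requested voxel size (e.g. 8x8x8 at 2 mm cannot contain the pons box).
The default pipeline grid is 48x48x48 at 3 mm — large enough that each VOI
has thousands of voxels, small enough that a 164-subject run takes seconds.

**Rendering.** `render_pet_volume` inverts the SUVr definition: before noise,
mean activity in VOI r equals `suvr[r] * pons_activity`, the pons is flat at
`pons_activity` (default 1000, arbitrary units — SUVr cancels the scale), and
background tissue is fixed at 0.25x the pons so Z-map displays have a nonzero
surround. Noise is multiplicative Gaussian per voxel (default fraction 0.05
in the pipeline; 0 gives exact round-trip recovery), clipped at zero to keep
intensities physical.

**Reference region.** Two modes: the whole pons label mean (default, exact
for phantoms) and a mid-pons box — a cube of edge 16 mm centered at the pons
centroid and intersected with the pons mask. The clinical description of the
box gives only its in-plane 16 x 16 mm dimensions; completing it as a cube is
the symmetric choice, and both modes are exposed (`ReferenceSpec`).

## Normative database and Z scores

Per VOI, the database stores the control sample mean and SD (n-1 denominator)
of mean SUVr, with the SD clamped below by `sd_floor` (default 1e-6) so
degenerate synthetic inputs cannot divide by zero; at least two controls are
required. The default Z orientation is `(subject - mu_db) / sigma_db`, so low
uptake gives negative Z and the clinical rule "Z below -2 is hypometabolic"
reads naturally; the opposite orientation, as some commercial reports print
the formula, is available and is the exact negation. The threshold test is
strict (`z < -2`); a value exactly at the boundary is normal. Voxelwise
mu/sigma grids support Z maps and threshold masks for display-style outputs.
VOI-level Z is computed from the VOI-mean SUVr (Z of the mean), not as the
mean of voxel Z values; with a voxelwise database the latter is available by
combining `z_volume` with the aggregation helpers.

## Cohort generator

The generator's defaults encode the published group statistics of the study
cohort: group sizes 40/38/44/42 (CN, MCI-NC, MCI-C, AD), per-(group, VOI)
SUVr means and SDs, demographics (age, sex ratio, education, APOE e4 carrier
fraction), baseline MMSE/CASI, conversion intervals and follow-up times, and
the trajectory coefficients of the marginal cognitive model.

**Regional SUVr.** Drawn per subject and VOI from Normal(mean, SD) truncated
at zero, by rejection (exact sampling; the bounds are >10 SD from every
default mean, so rejection is essentially free). Regions are independent
given the group by default. An optional *severity factor* (loading lambda in
[0, 1)) adds a shared per-subject standard normal to every regional draw and
to baseline cognition, inducing co-hypometabolism across regions and coupling
low uptake to low cognition — used to study Z-cognition correlations; the
default is 0 (minimal assumption).

**Baseline cognition and covariates.** The education (points/year) and
male-sex (points) coefficients of the marginal model are injected into the
baseline score draw, centered at the *realized* population values of the
generated demographics (the truncated-normal mean of education, the
configured male fraction), so the marginal group mean stays at the configured
value; the idiosyncratic SD is reduced so the marginal group SD matches the
configured one (floored at 10% of it should a custom configuration explain
more variance than the target allows). MMSE is rounded to an integer and
clipped to [0, 30]; CASI is clipped to [0, 100].

**Intervals.** Converter conversion intervals follow a truncated
Normal(3.70, 1.68) on [1, 8] years — one standard family matching the
reported mean, SD and range; truncation shifts the mean to ~3.87 y
(computed via `truncated_normal_mean`). Non-converter observation time is a
truncated Normal(4.34, 1.26) on [2, 7] (mean ~4.38 y). Other groups draw
their clinical follow-up from the group mean/SD truncated at zero, and a
converter's follow-up is floored at its conversion interval.

**Trajectories.** Visit 1 reproduces the subject's baseline scores exactly.
For visit v >= 2 the score is baseline + group offset(v) + noise, where the
offsets are the configured group-by-visit coefficients (visit 1 is the
reference, controls have no drift) and the noise is exchangeable within
subject: `sd * (sqrt(rho) u_i + sqrt(1-rho) e_iv)` with rho = 0.5 by default,
matching the working-correlation assumption of the downstream GEE. The
residual SD defaults — 2.0 MMSE points and 6.0 CASI points per visit — are
realistic test-retest noise for these instruments; both are configurable.
Requesting more visits than configured offsets is an error (no extrapolation
rule is defined). A subject is "demented" at a visit when MMSE < 20;
`converted_by_visit` gives the cumulative version.

**Instrument-ceiling censoring.** Clipping to the instrument range is a real
property of bounded scores, and it has measurable consequences in groups near
a bound: controls (MMSE 28.1 +/- 2.1, ceiling 30) lose upper-tail mass at
every visit, which attenuates covariate slopes estimated across the whole
cohort by roughly 8% and adds a ~0.3-point downward drift to control visits
relative to baseline. Rejection-truncation was evaluated as an alternative
and attenuates *more*, so clipping stays. Parameter-recovery tests therefore
check group-by-visit offsets within groups that sit away from the bounds (or
within the unclipped stratum), while the covariate coefficients are recovered
through the GEE at replicated cohort size, censoring included.

## Statistics

- **Marginal trajectory model:** statsmodels GEE, Gaussian family,
  exchangeable working correlation, robust (sandwich) SEs. The package owns
  the term coding — control group and visit 1 as reference levels,
  measurement number categorical, `male + education_years + group x visit`
  by default, any patsy right-hand side accepted.
- **Rank tests:** exact null distributions for n <= 10 — scipy's exact mode
  when there are no ties, and an in-package enumeration over group
  assignments (Mann-Whitney) or sign patterns (Wilcoxon, zeros dropped
  first) with average ranks when there are ties, which scipy's exact mode
  does not support. Larger samples use the tie-corrected normal
  approximation. All-zero paired differences report p = 1.0 with a NaN
  statistic (no evidence either way).
- **Correlations:** Spearman rho with average-rank tie handling; at least
  three pairs required, constant vectors are an error.
- **Diagnostic metrics:** sensitivity, specificity, PPV, NPV, accuracy with
  Clopper-Pearson exact 95% CIs; a metric with a zero denominator is
  reported as absent (None) with a warning, never coerced to 0. No ROC or
  threshold optimization — the -2 threshold is fixed by design.
- No multiple-testing correction is applied across VOIs in the rank tests.

## Reproducibility and problem sizes

Every stochastic function takes a seed; the pipeline derives stage seeds from
the run seed, stamps each output with the seed and a hash of the scientific
configuration (output location excluded), and identical config + seed reruns
are byte-identical. The test suite uses fixed seeds throughout; simulation
sizes were chosen as the smallest that make each check sharp: 10,000 draws
for moment recovery of the generators, the published 40/38/44/42 sizes for
end-to-end phantom recovery, 20x cohort replication for GEE coefficient
recovery, 2,000 replicates for the 5% null-calibration check of the
visit-wise test, and 25-replicate frequency checks for the visit-3
group-separation property.

## What the synthetic data does and does not show

The generator reproduces the *published group-level statistics* under
explicit distributional assumptions (normality, independence of regions given
group, exchangeable within-subject correlation). It does not emulate spatial
noise correlation, partial-volume or point-spread effects, registration
error, age-matching of the normative database (a pooled control database is
used), non-normal or skewed clinical score distributions, or any dependence
of conversion risk on APOE genotype. Consequently, passing tests demonstrate
that the pipeline is correct and that the generators hit their configured
targets — not that the clinical accuracy figures of any real cohort would be
reproduced. Indeed, with independent regional draws the synthetic converter
group separates more cleanly than real patients would, and the published
per-VOI hypometabolism percentages are not consistent with independent
normal regional distributions at the published means/SDs, so the generator
makes no attempt to force agreement with them.
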