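# Methods

This note documents the models behind each stage of titerkit, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical edge cases.

## Image model and counting procedures

A confocal stack is a `(Z, Y, X)` array of non-negative intensities with
plane 0 at the top of the acquisition and a default Z-spacing of 1.5 µm
(the spacing the counting conventions were developed for). Bacterial
nucleoids are diffraction-limited puncta; host nuclei are much larger,
dimmer blobs; follicle-cell or debris signal is removed with per-plane
binary *exclusion* masks (the programmatic stand-in for manual retouching).

**Thresholding.** `binarize_stack` supports Otsu, fixed, and percentile
policies, always recording the threshold used. An optional in-plane
Gaussian pre-smoothing (`smooth_sigma`, default off) is applied before
thresholding: with additive noise at ~20% of punctum amplitude, a smoothing
sigma of 1 px lowers the background tail by roughly fourfold while
attenuating a sigma-1.5 punctum by only ~30%, which is what keeps spurious
two-pixel components out of the counts. Masked voxels are excluded from
threshold estimation as well as from the result. Otsu on a constant image
warns and returns an empty foreground rather than failing.

**Counting.** Two procedures:

* *Full-volume 3D* (`count_puncta_3d`, default 26-connectivity, minimum
  2 voxels): connected components across planes, so a nucleoid visible in
  two adjacent planes is still one object. This is the computational analog
  of a person scoring every focal plane without double-counting, and is the
  reference procedure for stem cells and early egg chambers.
* *Stage-10 half-depth doubling* (`quantify_stage10_cyst`, default
  8-connectivity 2D, minimum 2 px): late-stage cysts are too large and too
  densely colonized for full-volume scoring, so planes are counted in 2D
  from the Z-center (the plane of largest foreground area — the widest
  section of the roughly football-shaped cyst; ties break toward the
  shallower plane) down to the deepest plane with signal, and the sum is
  doubled under the Z-symmetry assumption.

Connectivity defaults (8 in 2D, 26 in 3D) follow the common
particle-analysis convention; the 2-pixel/2-voxel minimum size suppresses
single-pixel noise. Both are configurable.

**Redundancy.** The doubling procedure counts per plane, so a nucleoid
straddling two focal planes is counted twice. `estimate_plane_redundancy`
quantifies this: over adjacent plane pairs, the fraction of components in
the deeper plane overlapping the shallower plane's foreground by at least
2 pixels (one-pixel grazes are deliberately ignored). On data resembling
the validation imagery this fraction is about 5%. The fraction is
*reported, not subtracted* by default — the published convention does not
state that totals were corrected — and `redundancy_correct=True` applies
`total × (1 − fraction)` for sensitivity analysis. Zero examined components
raises an error rather than returning a misleading 0.

## qPCR model

Amplification with per-cycle efficiency E multiplies template by (1 + E)
each cycle, so the threshold cycle is linear in log10 of input copies with
slope `m = −1/log10(1 + E)`; perfect doubling gives m = −3.3219 and the
inverse relation is `E = 10^(−1/m) − 1`. `fit_standard_curve` performs the
least-squares fit of Ct on log10(copies), requiring ≥ 3 points spanning
≥ 2 decades, and warns when efficiency leaves [0.90, 1.10] or R² drops
below 0.98 (practical plate-QC bounds; the method itself imposes none).
One curve is fitted per plate per gene.

Per-sample copies are the median of per-replicate `10^((Ct − b)/m)` values
(median rather than mean: a single late well distorts a mean of
exponentiated values; mean is available). No-amplification wells carry an
empty Ct — never a sentinel cycle like 40, which would fabricate copies for
negatives — and are excluded from aggregation; an all-sentinel sample is
reported as uninfected with 0 copies. Infection status is "any replicate
below the max-cycle cutoff" (default 40).

The relative ratio (wsp/rpl32) is computed from the absolute estimates and
errors out on a zero denominator. It is deliberately secondary: a c-fold
change in host gene copies changes the ratio by 1/c at constant bacterial
load, which is exactly the endoreplication confound absolute counts avoid.
Spike-in recovery controls pass through unmodified; no correction model is
applied.

`extrapolate_source_copies` converts reaction copies to per-fly burdens via
`copies × (extract volume / template volume) × dilution / flies`; it is
exact arithmetic on its inputs and is only as reliable as the extraction
and amplification consistency behind them.

## Test-selection decision tree

Each group is tested for normality (Shapiro-Wilk) and the pair for variance
homogeneity (Levene, mean-centered, the convention of the commercial
statistics packages this workflow grew out of;
median-centering/Brown-Forsythe by flag), both at a
diagnostic α of 0.05 (a choice; the workflow did not state one, and both
groups must pass for "normal"). Dispatch:

| normal | homogeneous | test |
|---|---|---|
| yes | yes | Student's t |
| yes | no  | Welch's t |
| no  | yes | Mann-Whitney U |
| no  | no  | randomization t |

Mann-Whitney uses the exact distribution for combined n ≤ 20 without ties
and the tie- and continuity-corrected normal approximation otherwise.
Kruskal-Wallis (tie-corrected H, chi-square reference) serves ≥ 3-group
stage comparisons; all values identical is a legitimate H = 0, p = 1.

**Randomization t-test.** "Randomization with bootstrapping" admits several
constructions; this one is: observed statistic = Welch t; null sample =
both groups centered to the pooled mean, then resampled with replacement
within group; p = (1 + #{|t*| ≥ |t_obs|}) / (1 + reps) (the add-one
estimator, so p is a valid p-value and never exactly 0). A pooled
label-permutation null is available via `mode="permutation"`. Replicates in
which both resampled groups are constant get t* = 0 (or ±∞ when the two
constants differ), which is conservative. Zero variance in both input
groups is an error.

## Subsampling power analysis

`power_curve` draws n values per group with replacement, independently from
each dataset, applies the selected two-tailed test, and reports the
fraction of iterations with p < α — for each n in 2–35, 10,000 iterations,
α = 0.01 by default (the validated procedure's settings). The test is
selected once from the full datasets (`auto_once`) and restricted to
Student, Welch and Mann-Whitney; a randomization-test verdict maps to
Welch inside the loop, both for cost and because the original procedure
used only t-variants and rank-sum tests. Per-iteration re-selection and
without-replacement draws exist for sensitivity analysis.

The inner loop is fully vectorized (one `(iterations, n)` array per group
per n, with a padded run-length computation for the Mann-Whitney tie
correction), which keeps a full 2–35 curve at 10,000 iterations under a
second. Each n gets an independent child of the seed sequence, so curves
are reproducible and individual n's are independently resampled.
Degenerate subsamples (both groups constant) count as non-significant.
Note that Mann-Whitney at n = 2 cannot reach p < 0.01 at all — a property
of the procedure worth knowing when reading the low-n end of a curve.
`min_n_for_power` returns the first crossing of a target proportion, or
none.

## Condition-level analyses

Summaries use medians throughout (titer distributions are right-skewed),
and percent-of-control is a ratio of medians, making it invariant to common
rescaling. Per-cell cluster titer is cluster total / cell count computed
per ovariole, then the median across ovarioles (the aggregation order was a
free choice; per-ovariole first keeps each ovariole one datum).
Cross-stage regressions fit the later stage on the earlier stage (R² is
orientation-invariant; only reported slopes depend on it). The drift check
compares the first k versus last k acquired records through the decision
tree and flags p < 0.01 by default; it treats acquisition order as the only
covariate.

## Synthetic generators: what they emulate, and what they do not

`make_stack` renders puncta as isotropic 2D Gaussian profiles
(sigma = radius/2, default radius 3 px, amplitude 1000 over background 100)
confined to a single focal plane, with a configurable fraction echoed at
60% amplitude into the adjacent plane to emulate nucleoids caught between
1.5 µm sections — the source of inter-plane redundancy. Host nuclei are
large 3D Gaussian blobs at lower peak intensity (300), so a single
threshold separates the populations; in real data that separation is done
by masking, which the generator therefore makes optional rather than
necessary. Noise is additive Gaussian by default (Poisson available).
Placement is dart-throwing with a 3D minimum separation and bounded
retries (failure raises a capacity error). The pixel size and punctum
diameter are free parameters, not calibrated to a microscope; optical
realism (PSF anisotropy, photobleaching, depth attenuation) is out of
scope. Passing counts on these stacks therefore demonstrates the counting
logic, not robustness to every optical artifact of real imagery.

`make_stage10_stack` distributes puncta so that the planes from the
Z-center to the bottom hold exactly half the total with the Z-center the
unique widest plane — the geometry under which half-depth doubling is
exact, used to validate the procedure's arithmetic in isolation from its
Z-symmetry assumption. Real cysts are only approximately symmetric, and
the doubled count inherits that approximation plus the ~5% redundancy.

`make_qpcr_plate` inverts the quantification model (Ct from true copies
plus Gaussian Ct noise, empty Ct for zero-copy wells), so with zero noise
curve fitting is the exact inverse of generation — the identity used in
round-trip tests.

`make_titer_dataset` draws normal or lognormal samples parameterized by
their theoretical median. The named `REFERENCE_CONDITIONS` encode the
validated study conditions: published per-stage medians (61.5 / ~1140 /
~22,500 under control food; 79 vs 55, 1180 vs 1260, 22,900 vs 8240 under
un-enriched vs yeast-enriched diets), with dispersions fixed once from the
published test statistics — GSC diet sd 25.5 (from Welch p = 0.017 at
n = 15 on a 24-unit median difference), stage-4 log-sd 0.30 (from
Mann-Whitney p ≈ 0.57 on a 7% median shift), stage-10 log-sd 0.35 (a
strongly significant ~2.8 log-sd separation). These are synthetic
stand-ins for undeposited per-ovariole tables: they reproduce the designed
medians, effect sizes and power profiles up to sampling error at the study
n, not the original data row for row. GSC values are normal clipped at
zero (counts; < 2% of mass affected at the yeast condition).

## Numerical choices and edge cases

* Coordinates are 0-based `(z, y, x)`; masks are exclusion masks (1 =
  removed), broadcast from a single plane when given one.
* Z-center ties break toward the lower (shallower) plane index, recorded
  behavior rather than an arbitrary argmax.
* A foreground spanning a single plane cannot support half-depth doubling
  and raises an error; an entirely empty foreground returns a zero result
  (an empty masked region is a measurement of zero, not a failure).
* Fixed thresholds outside the intensity range are rejected; percentile
  policies accept [0, 100].
* All generators and all stochastic procedures (randomization test, power
  curves) are pure functions of their arguments including the seed; power
  curves spawn independent seed-sequence children per n.
* p-values are clamped to [0, 1]; the randomization p uses the add-one
  estimator and so lies in (0, 1].

## Known limitations

* The stage-10 procedure's accuracy on real cysts depends on Z-symmetry
  and on the ~5% plane redundancy, neither of which the uncorrected
  doubled total accounts for; both are surfaced in `PunctaResult` so users
  can decide.
* Diffraction-limited doublets closer than the resolution limit are
  counted as one punctum by any thresholding method; the generators do not
  model this regime.
* The qPCR module starts from called Ct values; raw fluorescence
  processing, ΔΔCt workflows and multiplex chemistry are out of scope, and
  extraction-efficiency differences between sample types are not modeled
  (spike-in columns pass through uncorrected).
* Whether the original power procedure re-selected its test per iteration
  is not determinable; `auto_once` is the default because one test per
  comparison matches how such analyses are reported, and the alternative
  is provided.
* No multiple-testing correction is applied anywhere; the workflow this
  mirrors controls false positives by tightening α to 0.01 instead.
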