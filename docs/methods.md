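# Methods

This note documents the models and procedures implemented in `fuzzyord`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that make results
reproducible.

## Fuzzification of an ordinal scale

The scale is an ordered label set V = {v_1, …, v_k} (default: the
five-level severity terminology *Absent* < *Mild* < *Moderate* < *Severe*
< *Extreme*).  Each level receives a discrete weight function over the
integer grid 0..100, built from elicited perceptions by one of three
routes:

- **points** — count how often each grid value was named the level's
  representative point;
- **interval_centers** — collapse each elicited interval [l, u] to its
  midpoint (rounded half-up; for a single interval, centroid and median
  coincide there) and count midpoints;
- **whole_intervals** — spread each interval over its members with weight
  1/(u − l + 1), so every interval contributes total mass exactly 1 and a
  degenerate interval [x, x] is a unit point mass.

Resulting sets are not required to be convex or normal fuzzy numbers.  Two
normalised views are derived on demand and never stored: *membership*
(weights divided by their maximum — the modal value has membership 1) and
*prob* (weights divided by their sum).  Max-normalisation of membership is
a deliberate choice: it makes the self-component of the membership encoding
exactly 1 and the disjoint-support case bit-exact one-hot.  Binning
partitions the grid into consecutive runs of `granularity` values starting
at the grid minimum (last bin may be short); a bin is represented by the
arithmetic mean of its grid values — unbiased for full bins and
well-defined for the short one — and carries the sum of their weights, so
mass is conserved and the 1–99 qualitative range at granularity 3 gives
exactly 33 bins.

## Encodings

- **CoIED**: the centroid Σ x·μ(x) / Σ μ(x), invariant to positive
  rescaling of the weights, hence identical on raw weights, memberships or
  probabilities.  Values stay on the 0–100 scale; any standardisation is
  the model pipeline's concern.  `build_coied_map` records whether the
  per-level centroids are non-decreasing in scale order
  (`order_preserving`).
- **Weighted sampling**: draws from p_v(x) = μ_v(x)/Σμ_v.  The default
  mode samples every occurrence independently (`per_cell`), which is what
  makes within-row order reversals possible for overlapping supports;
  `per_label` draws once per level and reuses the value.  Both modes are
  pure functions of (column, fuzzy sets, seed, mode).
- **Membership**: level v maps to ⟨μ_{v_1}(x_v), …, μ_{v_k}(x_v)⟩ at v's
  modal value x_v; argmax ties break to the smallest grid value for
  determinism.  Cross-level lookups are exact grid matches (a value not on
  another set's grid contributes 0), so membership vectors are intended for
  sets on a common grid, not for mixed binned/unbinned sets.
- **Baselines**: rank index (v_i → i−1), one-hot, rank-hot.

## Stratum comparison and qualitative summary

Per level, the two strata are compared with the two-sample two-sided
Kolmogorov–Smirnov test (shape) and the Mann–Whitney U test with tie
correction (location; exact null for small tie-free samples, normal
approximation otherwise).  Values come from one of three sources: pooled
interval endpoints (`extremes`, two per respondent), interval midpoints
(`centroids`), or representative points (`rps`).  No multiplicity
correction is applied across levels; p-values are reported raw.

The qualitative survey (a uniform value in 1–99, answered with a label) is
summarised per width-3 bin: counts per label, the modal label (ties break
to the lower scale rank), and an escalating prevalence class —
*superiority* (mode), *majority* (mode share > 0.5), *statistical majority*
(majority plus a 1-df χ² goodness-of-fit between the two most common labels
against equal expectation, p < 0.05, no continuity correction; a
single-label bin is tested against a second count of 0).  Escalation
guarantees monotonicity of the classes by construction.

## Benchmark harness

`nested_cv_evaluate` scores one (model, encoding) pair with nested CV:
5 shuffled outer folds for unbiased MAE/R² estimation, 3 inner folds for
hyperparameter tuning by grid search on negative MAE.  Grids are small
published defaults — kNN neighbours {3, 5, 7, 11}; LASSO α on a log grid
10⁻³..10; SVR C ∈ {0.1, 1, 10, 100} with γ = "scale"; RF with 100 trees and
min_samples_leaf ∈ {1, 5} — and can be overridden per call.  Distance- and
penalty-based models (kNN, SVR, LASSO) standardise all design-matrix
columns inside each training fold; the forest receives raw values.
Confidence intervals are 95% t-intervals over the outer-fold scores; the
stochastic weighted-sampling encoding is re-drawn and re-scored 10 times
with derived seeds and its fold scores pooled (the pooled mean equals the
mean of per-repeat means).  Missing data are out of scope: the feature
table forbids missing targets and the generator emits complete data.

### Random-forest order invariance

Regression-tree splitting ranks feature values; it never measures their
distances.  Any order-preserving rescaling of an ordinal feature — a
monotone CoIED map — therefore grows the same trees on the same training
rows, and predictions on those rows are identical
(`rf_order_invariance_check` fits without bootstrap resampling so that
every row is a training row of every tree, and asserts exact equality).
Held-out rows are only *almost* identical: scikit-learn places split
thresholds at midpoints between adjacent training values, so a held-out
row whose level is absent from a node's training sample is interpolated
into the gap, and midpoints of ranks need not agree with midpoints of
unequally spaced centroids.  `rf_order_invariance_report` quantifies both
sides: with the default synthetic task, training MAE difference is exactly
0 while a few percent of out-of-fold rows differ, moving out-of-fold MAE by
well under 1%.  This is an implementation artifact of threshold
interpolation, not a failure of the ordering principle.

## Synthetic generators

The generators emulate the *structure* of a two-strata elicitation study
and a PROM prognostic task; they do not attempt distributional realism of
any particular deposited dataset.

**Interval survey.**  Per respondent and level: a perception center
~ Normal(level_center, center_sd), an interval half-width
~ |Normal(half_width_mean, half_width_sd)|, the interval clip(center ±
half-width) rounded to the integer grid, and an RP ~ clip(center +
Normal(0, rp_jitter_sd)).  The shipped default profiles
(`data/default_profiles.yaml`, version 1) place doctor centers at
9/26/47/67.5/88 and patient centers at 13.8/26.6/41.3/58/70.8 with
center_sd 8, half-width 10 ± 4 and RP jitter 5 — an "inspired-by"
emulation of the reported stratum contrast (laypeople compress the upper
half of the scale and inflate the bottom), never parameter estimates.
Clipping at the scale boundaries biases interval midpoints inward for
levels near 0 or 100; the parameter-recovery checks therefore use interior
centers, where the midpoint estimator is consistent (recovery within one
grid unit at n = 1,000 respondents, center_sd 5).

**Qualitative survey.**  A uniform integer value in 1–99; the label is
chosen with probability ∝ exp(−(value − center)²/(2·center_sd²)) under the
respondent's stratum profile.  As center_sd → 0 this converges to the
nearest-center label.  n = 990 gives on average 10 answers per value,
matching the density the binning summary was designed for.

**Latent-severity outcome dataset.**  336 rows × 15 features: gender, age,
intervention type, 3 continuous scores, 9 ordinal items.  Each ordinal item
has a latent severity z ~ Normal(μ_f, latent_sd) clipped to [0, 100]
(feature means spread over 25..75, latent_sd 25); the recorded label is the
cutpoint bin containing z, with default cutpoints 5/15/30/60 — a
floor/ceiling-style design whose bins [0,5), [5,15), [15,30), [30,60),
[60,100] compress low severities and stretch the top, as severity
instruments often do.  The target is linear in the latent severities
(coefficient 0.08 each), the continuous scores (0.2/0.1/0.1), age (−0.02),
gender (+0.3) and intervention type, plus Normal(0, 0.5) noise.  Because
the *latent values*, not the ranks, drive the target, equally spaced rank
encoding is misspecified exactly to the extent the cutpoints are
non-uniform; the ordinal items carry most of the signal so that the
encoding of those items is what the benchmark measures.  Under these
defaults kNN with the CoIED encoding beats kNN with rank encoding
consistently (≈5–8% lower mean MAE over 10 seeds).  A "matched" survey
profile places zero-noise elicitations at the cutpoint-bin midpoints,
which is what a rater who perceives the labels as the bins would report;
fuzzifying it and taking centroids recovers those midpoints, closing the
loop between the elicitation and encoding halves of the package.

**What passing these checks does and does not show.**  The generators are
complete-data, Normal-noise idealisations: no respondent inattention or
"dirty" answers beyond what the cleaning rules can name, no
device-dependent elicitation artifacts, no correlated ordinal items, no
informative missingness.  Results on them validate the machinery and the
qualitative directions (stratum separation where profiles differ, encoding
benefit under rank misspecification); they say nothing about effect sizes
on real clinical data.

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; every
generator and the sampling encoding are pure functions of their parameters
and seed.  Grid values are integers 0..100; cell parsing rounds half-up.
Mass-conservation assertions use absolute tolerance 1e−9; exact-agreement
assertions (brute-force oracles, train-row invariance) use equality.  The
statistical calibration checks run 200 null replicates at 100 respondents
per stratum (fraction of p < 0.05 observed ≈ 0.03 — the KS test is
conservative under heavy integer ties) and 100 shifted replicates at 200
per stratum; the benchmark checks run 10 seeds of the 336-row task.  These
sizes give stable results while keeping the whole suite fast.

## Known limitations

- Membership encoding across differently binned sets silently yields zero
  cross-memberships (exact grid lookup); keep sets on a common grid.
- The χ² prevalence test with a zero second count is a convention, not an
  inferential claim; single-label bins are trivially "statistically
  majoritarian" once they hold ≥ 4 responses.
- Representative points outside their interval are kept (flagged, not
  dropped): intervals and RPs are treated as separate elicitations.
- Confidence intervals over 5 outer folds are t-intervals on 4 degrees of
  freedom — wide and only approximately calibrated; swap in more repeats or
  a bootstrap for tighter intervals.
- No multiple-testing correction across levels, by design; apply one
  downstream if levels are screened jointly.
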