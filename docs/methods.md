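# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test suite, the numerical choices, and the limits of
what the passing tests demonstrate.

## Screen normalization and hit calling

Raw luminescence is mapped per plate to percent-of-control (poc) using
the plate's own DMSO (negative) and protective positive-control wells:
`poc = 100 · (signal − mean_DMSO) / (mean_positive − mean_DMSO)`. The
mean DMSO poc of a plate is exactly 0 and the mean positive-control poc
exactly 100 by construction; normalization is invariant to per-plate
affine changes of the raw signal (detector gain/offset), which is the
point of per-plate anchoring.

The hit rule has two one-sided parts applied to the replicate-mean poc
of each compound × concentration: (i) mean poc ≥ 3 × the plate's DMSO
standard deviation on the poc scale (unbiased n−1 estimator), and
(ii) mean poc > 20%. Both parts point toward rescue: the screen looks
for protection, and a compound that *lowers* viability is never a hit.
The DMSO spread is taken per plate (no cross-plate pooling), matching
the per-plate normalization; whether the original rule used the raw or
poc scale is not documented, and the poc scale is assumed here. A
*robust hit* is a hit at every tested concentration; single-
concentration hits remain in the output. Replicates are averaged before
the rule is applied rather than called individually.

Under a null screen the per-test false-hit probability is bounded by
the one-sided normal tail at 3 s.d. (≈1.35 × 10⁻³), and in practice is
far smaller because replicate averaging shrinks the compound mean's
spread by √n and the 20% floor usually dominates the 3-s.d. term.

## Hill-model potency estimation

All potencies use the four-parameter Hill form
`response(d) = background + (signal − background) / (1 + (midpoint/d)^slope)`,
in which a positive slope gives a curve increasing in dose and a
negative slope a decreasing one, and the response at `d = midpoint` is
exactly halfway between the asymptotes for any slope.

Numerical choices:

* residuals are minimized with `scipy.optimize.least_squares`
  (Levenberg–Marquardt when unbounded; trust-region reflective when the
  viability conveniences apply their soft asymptote bounds of
  background ∈ [−10, 50]% and signal ∈ [50, 150]%, both overridable);
* the midpoint is optimized as log10(midpoint) for conditioning of
  serial-dilution designs; convergence tolerance 1e-8 on relative
  parameter change;
* multi-start: the midpoint is seeded at the geometric median dose and
  at the dose whose mean response is closest to half-maximal; the slope
  at ±1 (or the fixed value); asymptotes at the low-/high-dose response
  means and swapped. The best final cost wins.
* weighting defaults to *relative*: residuals are divided by
  `max(|model|, 5% of the observed response range)`. This is the
  maximum-likelihood weighting when the error scales with the expected
  response, which is both how the synthetic generator draws noise and
  the typical behavior of luminescence and qPCR readouts. Plain
  unweighted least squares is available (`weighting="none"`). The
  weight floor is a constant derived from the data, not from fitted
  parameters — flooring on the fitted span lets the optimizer inflate
  the span to cancel the weights.
* the Hill form is invariant under swapping the asymptotes and negating
  the slope; when the slope is free the fit is canonicalized to
  signal ≥ background so the reported labeling is deterministic.
* replicates enter as pooled points, not means.

Censoring and conventions: a fitted response window narrower than 5
response units, or a midpoint outside the dose range × [1/100, 100], is
censored (`no_effect` / `below_range` / `above_range`) with no reported
midpoint. Binding fits (`fit_kd`) fix the slope at −1 (one-site
competition); a Kd above the top tested concentration is reported as
4/3 × top — 40,000 nM for the standard 30,000 nM top, read as
">30,000 nM" — and a Kd below the lowest tested concentration is
flagged `repeat_lower_top`, the convention being to re-measure with a
serial dilution starting lower. Protection fits (`estimate_ec50`)
expect increasing curves and toxicity/kinase fits (`estimate_ic50`)
decreasing ones; a fitted slope of the wrong sign is flagged, not
silently discarded. The viability fits leave the slope free; whether
the original analyses fixed it is not documented.

## Mass recalibration

An initial broad-tolerance search (±10 ppm precursor, ±0.6 Da fragment)
supplies anchors: engine-A PSMs with score ≥ 30 belonging to proteins
with ≥ 3 distinct peptide identifications at that level. Independent
linear transformations `corrected = slope · measured + offset` are
fitted for precursor and fragment masses to minimize the mean-square
deviation from theoretical masses — precursor in relative (ppm-error)
space and fragment in Da, matching the units of the respective
tolerance windows. Both are linear least-squares problems with
closed-form solutions, so the post-calibration mean-square deviation on
the anchor set can never exceed the pre-calibration value, and a
noiseless linear distortion is inverted exactly. After correction, PSMs
outside ±4 ppm (precursor) or ±0.3 Da (any fragment) are dropped.
Degenerate anchor sets (all masses equal) are rejected as
rank-deficient.

## Dual-engine validation, merging, grouping, FDR

Per engine, a protein is validated by ≥2 *unique* peptides scoring
above T1, or any single peptide above T2; peptides above T3 are then
attached to validated proteins. Unique means the peptide's accession
list has exactly one member. Score comparisons against T1/T2/T3 are
strict (> T), while the calibration anchor filter is inclusive (≥ 30);
the two rules are worded differently at their sources and both are
configurable. Engine protein scores are sums of best peptide scores
(the Mascot convention), applied identically to the Phenyx-like engine,
whose score is treated as an opaque monotone quality measure.

Merging discards any spectrum the two engines assign different peptide
sequences (before counting, the conservative reading), takes the union
of validated proteins, and groups proteins sharing any accepted peptide
by single-linkage closure (verified against a brute-force
connected-components oracle in the tests). Spectral counts per
condition × replicate count each spectrum once even when both engines
matched it.

FDR runs the identical chain on the reversed-sequence half of the
search space: protein FDR = validated decoy groups / validated target
groups; peptide FDR = accepted decoy peptides / accepted target
peptides, T3-level additions included on both sides and peptides shared
between the halves excluded from the numerator. Verdicts are evaluated
against the <1% protein and <0.1% peptide gates.

## Competition-specificity scoring

For each of three measures — spectral counts, engine-A protein score,
engine-B protein score — every value is replaced by its mid-rank
quantile `(rank − 0.5)/n` (ties averaged) within the condition-wide
distribution across all groups, making the downstream test invariant to
any strictly monotone transform of the measure. Cells missing from the
profile table are filled first: counts as 0 (absence under competition
is evidence of competition) and scores as the condition-minimum value,
i.e. the condition-minimum quantile; filling values before the
transform keeps pool membership identical across conditions, so one
group's absence cannot shift another group's ranks.

Per group and measure, a one-sided permutation test on the condition
labels uses the statistic mean(non-competed quantiles) −
mean(competed quantiles), with
`P = (#permutations with statistic ≥ observed + 1)/(#permutations + 1)`.
Label assignments are enumerated exhaustively up to 12 total replicates
(all C(8,4) = 70 at the standard 4+4 design, agreeing exactly with a
brute-force oracle) and by seeded Monte-Carlo above that. The three
P-values are combined by Fisher's method: the upper χ² tail of
−2 Σ ln pᵢ at 6 degrees of freedom. Groups with combined P below 0.05
are specific binders.

This permutation-on-quantiles construction is a concrete, conservative
interpretation of a competition statistic whose original mechanics are
not fully public; the quantile step, the three measures and the Fisher
combination are the documented modifications it honors. Whether the
original inputs were one- or two-sided is unknown; one-sided toward
reduction is used, since only reduction under competition indicates
specific binding. Note the granularity: at 4+4 replicates the smallest
attainable per-measure P is 2/71 ≈ 0.028, reported per group as
`min_attainable_p`. The discreteness makes specific-binder calls
conservative — null simulations show a type-I rate near 0.015 at the
nominal 0.05 — so the calibration guarantee is one-sided (never
anti-conservative), which the acceptance tests assert.

Fold reduction is median(competed counts)/median(non-competed counts)
over the four replicate counts per condition (the median of four being
the mean of the middle two); its complement in percent and the mean
non-competed count (bubble size) annotate the bubble-plot export. A
zero non-competed median leaves the ratio undefined and excludes the
group from the plot with a logged reason.

## Synthetic-data model

The generators emulate the statistical structure the analysis assumes,
with defaults encoding the study conditions:

* **screen** — 384-well plates, compounds at 1.5 and 0.5 µM in
  duplicate, ≥2 DMSO and ≥2 positive-control wells per plate, Normal
  noise with s.d. = 10% of the expected signal; planted hits
  interpolate linearly between the death baseline and the full-rescue
  level by their rescue fraction.
* **curves** — responses drawn around the exact Hill value at each dose
  of a serial-dilution design (default 11-point 3-fold; binding from
  30,000 nM), s.d. = noise_cv × |model value|, dose 0 never included.
* **pull-down** — a background proteome (log-normal mean spectral
  counts, e^N(2.3, 0.8²)), planted true targets whose count *and*
  peptide-score means are multiplied by the competition effect
  (default 0.1) in the competed condition, reversed-accession decoys,
  and optional spurious target-database matches drawn from the same
  null score distribution as decoys (off by default; used to compare
  decoy FDR estimates against realized false-target rates). Counts are
  negative-binomial (dispersion 0.3) rather than Poisson, giving
  realistic overdispersion; no per-protein count distributions were
  ever published for the real experiment, so these defaults are
  unconstrained by data. Four exchangeable replicates per condition
  stand in for the two biological × two technical hierarchy, which is
  not modeled. Peptides are random tryptic-like sequences with
  pyteomics-computed precursor and b/y fragment masses, distorted by a
  configurable linear error model (slope, offset, jitter) that is
  exactly invertible at zero jitter. Engine scores in the profile-level
  generator are increasing noisy functions of the *expected* count, so
  competition moves counts and scores coherently while score noise
  stays independent of count noise under the null — the regime in which
  Fisher combination of the three measure P-values is calibrated.
* determinism — one `numpy` Generator per simulate call, seeded from
  the config; fixed seeds give bit-identical tables.

What passing tests do *not* show about real data: no chromatographic,
isotope or raw-spectrum structure is modeled (the pipeline consumes
search-engine tables); real engine scores correlate with realized
counts within a sample, which can make the three combined P-values
positively dependent and the Fisher combination less conservative than
in the independent-noise simulations; plate artifacts
(row/column/edge effects) are absent by design, and none are corrected
for.

## Problem sizes used in the checks

The statistical suites run at sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes: 100 seeded repeats per potency
recovery, 200 null screens (plus 50 with planted rescuers), 100 null
pull-down datasets of ~88 proteins for type-I calibration, 40 datasets
for power, and 50 full PSM-level simulations for the FDR comparison.
The whole suite completes in about a minute on one CPU.

## Known limitations

* The Decontaminator-style statistic is an interpretation (see above);
  its absolute P-values should be read with the granularity floor in
  mind at small replicate numbers.
* Kd censoring reports 4/3 × top as the ">top" code for any top
  concentration, generalizing the 40,000 nM convention defined for the
  30,000 nM design.
* Biphasic (bell-shaped) dose-response behavior is not modeled; such
  curves fit poorly and should be censored or flagged by eye.
* Isoform-level quantification beyond accession-list handling, PTM
  localization and spectrum rescoring are out of scope.
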