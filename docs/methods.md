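# Methods

This note documents the models, defaults and design choices behind
`thromboquant`, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, what the synthetic data do and do not emulate,
and where the design was genuinely open.

## Image quantification

**Segmentation.** The pipeline is fixed in order: linear 1st–99th percentile
contrast stretch ("auto-enhance"), a length-3 median filter applied along
rows and then columns (an edge-preserving interpretation of horizontal +
vertical filtering), thresholding, then a binary close followed by open with
a 3×3 square structuring element. The default threshold is Otsu — an
automatic, reproducible stand-in for manually set thresholds — with a
`('fixed', t)` override. A constant image under Otsu returns 0% coverage by
convention (there is nothing to threshold). Otsu assumes a foreground worth
finding; on fields below roughly 1–2% coverage the percentile stretch can
re-span the background noise and the threshold becomes unreliable, which is
the main practical caveat of the automatic default.

**Integrated feature size.** IFS = Σf²/Σf over the connected-component areas,
i.e. the mean feature area weighted by feature area. Properties used in
testing: IFS([A]) = A; min f ≤ IFS ≤ max f; merging two features never
decreases it; empty fields give 0. An equivalent description plots the
cumulative contribution of squared areas, ranked from small to large, against
total feature size; the summation form is what is implemented, since the
graphical form adds nothing numerically.

**Morphological score.** The 0–5 score is a visual rubric in the assay
(0 = no adhesion … 5 = full thrombi with large aggregates). The package
provides a deterministic proxy driven by coverage and the largest feature
area, with calibration cut-offs: score 0 below 0.5% coverage; scores 1/2
split at 10% coverage when all features are below the single-platelet cut
(50 px at the default 0.207 μm pixel size); scores 3/4/5 split at largest
features of 500 and 2,000 px, with ≥25% coverage also promoting to 5. These
defaults are a declared approximation chosen for testability, not a
biological calibration; anyone applying the proxy to real images should
recalibrate the cut-offs against scored examples.

**Stable adhesion.** A pixel is stably adhered when it is above background in
at least a `persistence` fraction of frames (default 1.0, i.e. all frames of
the 1-min, 2-s-interval series) and its mean absolute frame-to-frame
differential stays below 30 grey levels (half the default foreground/
background contrast). Background defaults to an Otsu threshold on the
temporal mean image.

**Thrombus volume.** Each z-stack (default 0.5 μm spacing) is thresholded
with one global threshold; volume per unit area is occupied voxels × voxel
volume / field area — the mean occupied height in μm. Columns are not forced
to be contiguous (no fill-in); a stack whose two Otsu classes differ by less
than 10 grey levels is treated as empty, which prevents the threshold from
splitting pure background noise.

## Panels, normalization, variability

Replicate runs are aggregated to cell means (duplicate run keys are an input
error, not extra replication). Each parameter is normalized 0–10 across the
surface panel: x → 10(x − min)/(max − min), column-wise; a degenerate column
(max = min) maps to 0 with a warning, since "no dynamic range" should not
read as mid-scale signal. Normalization bounds are frozen on the
healthy-control panel and reapplied to patient data, so patient values are
expressed on the control scale and may legitimately fall outside [0, 10].
When panels from different shear rates are compared, each shear condition is
normalized within itself by default; shared bounds are a caller choice via
`apply_bounds`.

Variability is summarized per parameter as intra-individual CV (per
subject × surface: s.d. over days / mean, averaged over subjects and
surfaces), inter-individual CV (per surface: s.d. of subject means / grand
mean, averaged over surfaces), and their ratio. Pooling over surfaces is the
unweighted mean of per-surface CVs. `pooled_ratio` (mean inter CV / mean
intra CV across parameters) is the cohort-level summary; it is much more
stable than any single parameter's ratio when only nine surfaces contribute.

## Clustering and bootstrap support

Agglomeration is Euclidean/complete-linkage, written in-package so the
tie-break is fully specified: among all minimal-distance pairs, the
lexicographically smallest (id_a, id_b) merges first, with leaves numbered in
input order and internal nodes in creation order. This makes merge sequences
a pure function of the data — verified against an exhaustive O(n³) oracle and
against scipy on tie-free data.

Cluster support uses multiscale bootstrap: columns (parameters) are resampled
with replacement at ten relative sizes r ∈ [0.5, 1.4]; per cluster the
recovery frequency BP(r) is recorded; z(r) = Φ⁻¹(1 − BP(r)) is fitted by
weighted least squares (delta-method binomial weights) to v·√r + c/√r; and
AU = 1 − Φ(v − c). Only scales with 0 < BP < 1 enter the fit, at least three
are required, and clusters recovered never/always at every scale are clamped
to AU 0/1 with a flag. Resampling columns when judging surface clusters
mirrors the reference convention for this kind of two-way panel. Default
n_boot is 1,000 per scale for routine work; a full-fidelity run simply raises
it (10,000 randomizations total matches the original design). BP at the scale
nearest r = 1 is reported as the ordinary bootstrap probability.

Cutting the surface tree at k = 3 and ranking clusters by mean normalized
value (ascending) yields types I–III; ties break by cluster size then lowest
surface index. An all-identical panel has no 3-cluster structure and is
rejected. A generic leave-one-out report (drop one parameter or surface,
re-cluster, ARI against the full partition) supports sensitivity analyses
without asserting any particular conclusion.

## PLS receptor models

PLS1 is implemented as textbook NIPALS on mean-centered (optionally
unit-scaled) predictors: w ∝ Xᵀy, t = Xw, deflation by t·pᵀ and t·q;
coefficients B = W(PᵀW)⁻¹q. Thrombus type is coded ordinally 1/2/3 on one
numeric axis (one-hot PLS-DA is out of scope); predictions round half-up and
clamp to [1, 3]. Predictors are centered but not scaled by default because
assignment entries are already 0/1 and panel values share the 0–10 scale.
Variance explained is reported as per-component X-variance. Cross-validation
defaults to leave-one-out — deterministic and appropriate at n ≈ 52. Key
anchors: full-component PLS equals OLS on full-rank designs (so the
machinery is checked against closed-form regression), coefficients scale
linearly with y, and sklearn's PLSRegression reproduces the predictions to
1e-10 in the test suite (as an independent cross-check, not a dependency).

The low-shear refit recomputes centering/scaling on the low-shear surfaces
("separate-scaled"); the exclusion mode drops a named receptor column —
surfaces left without modeled receptors then predict the intercept, which is
exactly the intended meaning of removing a receptor's contribution.

## Patient profiling

Reference ranges aggregate each control subject to its per-cell mean first,
then take mean and s.d. across subjects, so the reported s.d. is the
between-subject (inter-individual) spread — the right yardstick for judging
whether a patient lies outside the healthy population, as opposed to repeat
variability. The significance map flags cells beyond mean ± 2 s.d.; cells
whose s.d. cannot be estimated (one subject) are untestable and excluded from
counts. Subtraction tests use Student's pooled-variance t (Welch optional) on
patient runs vs control subject means, with no multiple-testing correction by
default (per-cell α = 0.05 presentation; Benjamini–Hochberg available as an
opt-in extension).

Calibration facts, all recomputed by the test suite and acceptance script:
against the *population* reference the two-sided flag rate on null patients
is the normal 2-s.d. exceedance (≈4.6%), and a −3 s.d. deficit is always
flagged. Against a reference *estimated* from 6 controls the same map flags
null cells at roughly 11% and catches a −3 s.d. deficit about 94% of the
time — 2·ŝ with 5 degrees of freedom has t-like tails. The package reports
both; users with small control panels should read the map as a screening
device, not a calibrated test.

## Synthetic data: what it emulates, and not

Scenes are binary-ish platelet fields: axis-aligned rectangles (default;
minimum side 3 px, ≥3 px clearance placed by rejection sampling with a
10,000-try budget) or ellipses, rendered at foreground 80 / background 20 on
the 8-bit scale with Gaussian noise s.d. 5, 0.207 μm pixels. Feature areas
are lognormal (median 100 px, shape 0.6). The rectangle default and the
contrast/noise levels are chosen so the default segmentation recovers the
truth mask pixel-exactly on noise-free scenes, making "measured = truth" a
meaningful test; an `aggregate` mode allows overlaps and records merged
component areas. Time series hold a chosen fraction of features in every
frame (to one feature's granularity) and give the rest random visibility
windows; z-stacks give each footprint pixel a contiguous occupied run from
the bottom slice, so volume truth is exact by construction.

Planted panels place three thrombus types at overall activation levels
2, 2+Δ, 2+2Δ with Δ = separation × noise s.d. (default 4 × 0.75), small fixed
per-parameter offsets, three replicates per surface. The planted receptor
model uses intercept 1.003 and weights (+0.543, +0.436, +0.542, +0.218,
−0.114, +0.465, +0.446, −0.106, +0.113) for (GPIb-V-IX, GPVI, CLEC-2, α2β1,
α5β1, α6β1, αIIbβ3, αvβ3, CD36) — a distinct-valued hierarchy with strong
adhesion/signalling receptors, a moderate α2β1 and weak/negative minor
receptors. Surfaces engage 1–5 receptors, resampled so the noise-free
response stays inside the 1–3 class range; by exhaustive enumeration no
feasible receptor subset lands within 0.023 of a class-rounding boundary, so
zero-noise classification is well-posed. Cohorts follow a two-level normal
model (cell mean + subject effect × inter s.d. + day effect × intra s.d.);
defaults mirror the reference design: 9 surfaces × 6 parameters, 6 subjects ×
4 days, inter s.d. 0.9 = 3 × intra s.d. 0.3, patient values planted exactly
at cell mean + shift × inter s.d.

What passing tests therefore show: the operators recover known truth under a
controlled noise model. What they do not show: robustness to uneven
illumination, debris, focus drift, red-cell shadows, platelet morphology, or
non-Gaussian biological variation — none of which the generator attempts to
render.

## Numerical and reproducibility choices

Every generator and the bootstrap take a mandatory integer seed
(`numpy.random.default_rng`); the pipeline fans one master seed into
per-stage children via `SeedSequence(seed, spawn_key=(stage,))`, and all
numeric CSV output is written at 10 significant digits, so a re-run with the
same seed is byte-identical — asserted in the test suite. Degenerate-input
conventions: empty feature set → IFS 0 and score 0; constant image → 0%
coverage; degenerate normalization column → 0 with warning; single-subject
reference cells → untestable. Problem sizes in the routine tests are scaled
to what the statistics need rather than to the original assay (e.g. 192–256
px fields, 10–12-slice stacks, n_boot 1,000 with 10–12 surfaces for repeated
bootstrap runs, 52 surfaces elsewhere); each size is stated in the tests
that use it.

## Known limitations

- The morphological-score proxy is a rubric stand-in; its cut-offs are not
  biologically calibrated.
- Otsu-based segmentation degrades below ~1–2% true coverage; use a fixed
  threshold there.
- The β-weight model treats an ordinal class as numeric; misassignment
  concentrates at class boundaries and cannot reach zero when the regression
  target is the rounded class itself.
- The 2-s.d. significance map is calibrated against population parameters;
  with few controls it over-flags (t-tails), as quantified above.
- No registration, stitching, spectral unmixing, flow physics or signalling
  simulation; experimental ingest beyond TIFF/CSV is out of scope.
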