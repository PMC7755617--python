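# Methods

## Scope and model

`hippoquant` quantifies the two MRI biomarkers of hippocampal sclerosis (HS)
— hippocampal volume loss and T2 elevation — from a coregistered dual-echo
fast-spin-echo acquisition plus left/right hippocampal masks, places them in
normative context, and renders a structured quantitative report (QReport).
Segmentation itself is an input: masks are consumed, never produced. The
package also implements the complete reader-study statistics battery used to
validate such reports clinically, together with a parametric simulator of
rater responses.

### qT2 mapping

With two effective echoes the monoexponential decay S(TE) = S0·exp(−TE/T2)
is exactly identified:

    T2 = (TE2 − TE1) / ln(S1/S2),    S0 = S1·exp(TE1/T2).

This closed form equals the two-point least-squares fit, so no iterative
solver is used. Default echo times are TE1 = 30 ms and TE2 = 119 ms
(TR 7600 ms, metadata only), the dual-echo relaxometry protocol the default
configuration mirrors. A voxel is flagged invalid — NaN outputs, `valid = 0`
— when the late echo sits at or below the noise floor (ε = 10⁻⁶ signal
units), when the signal fails to decay (S2 ≥ S1, an infinite or negative
T2), or when the fitted T2 leaves the physical clamp range (default
[1, 2000] ms; such voxels are additionally marked `clamped`). Invalid voxels
are never imputed; every downstream summary masks on the validity flag, and
the fraction of invalid/clamped voxels inside the hippocampal ROI is the
report's fit-QC measure. How a clinical pipeline should treat non-decaying
voxels is genuinely under-determined; the explicit flag-and-exclude scheme
was chosen to make failures visible rather than silent.

### Volumetry, ratios, and long-axis profiles

Global volume is voxel count × voxel volume (exact). Global qT2 is the mean
of valid-fit T2 over the mask (median available by configuration; the mean
is the default because the normative bands are Gaussian). L:R ratios are
100·left/right; both the volume and qT2 ratio are reported. Because the
labelling of published unilateral ratios is ambiguous (an "unaffected:
affected" label printed next to values that imply the opposite), the package
reports plain left:right and leaves side attribution to the flagging rule.

The long axis of each hippocampus is the leading principal component of the
in-mask voxel world coordinates, sign-fixed so its world-anterior component
is positive. This is a deterministic, self-contained stand-in for
group-template long-axis alignment, which needs an external template
database; on curved-tube phantoms it agrees with the generating centerline
chord to within a few degrees, and it is stable to ±1% boundary voxel
perturbations (≤2° direction change). Masks with fewer than 10 voxels or
without a dominant axis (leading principal value < 1.05× the second) are
rejected.

Profiles partition mask voxels by projection onto the axis into 20
equal-width bins (configurable; the granularity matches typical report
figures) spanning the 2.5th–97.5th percentile of projections; projections
outside the span are clipped into the end bins, so bin volumes sum to the
total mask volume *exactly*. Positions are normalised arc fractions with
0 = posterior, and cross-subject correspondence is by normalised position (a
stand-in for template correspondence). Cross-sectional area is per-bin
projected volume over bin width, with each voxel's projected extent spread
fractionally across the bins it overlaps: a hard count/width estimate
aliases against the voxel lattice whenever the bin width is close to, but
not a multiple of, the slice spacing (on a 40 mm straight cylinder with
1 mm voxels and 20 bins the hard estimate oscillates by ±35%; the
anti-aliased estimate is within 2% of πr²). Bin *volumes* remain exact hard
counts. Per-bin qT2 is the mean (or median) of valid fits in the bin, NaN
when none.

### Normative model and flagging

All reference bands are mean ± 1.96 SD over a healthy cohort — the central
95% Gaussian interval — with no covariate adjustment (the reference is an
age-matched pool; age/sex/ICV-adjusted norms are out of scope). A model
needs ≥ 20 subjects (SD estimates below that are unstable; the published
reference used 111). Global volume/qT2 norms are assumed to follow the same
±1.96 SD convention as the ratio bands shown in report figures. A shipped
default model carries the published ratio bands only — volume ratio
[88.9, 110.6]%, qT2 ratio [93.7, 104.2]%, n = 111 — because absolute volume
and qT2 norms are scanner- and protocol-specific.

Flagging is explicit machine advice, labelled as such in the report. Each
referenced metric is low/high outside its band. The overall impression is:
an abnormal ratio names the implicated side (lower volume or higher qT2);
if the volume and qT2 ratios implicate opposite sides, bilateral; if ratios
are normal but both sides' absolute volume is low or both sides' qT2 high,
bilateral — this operationalises the clinical observation that bilateral
disease can leave ratios near 100%, which is exactly the case where a
reader most needs support. The aggregation rule is this package's own.

Calibration: against a model built from 111 simulated controls, healthy
draws are flagged per metric at ≈5.4% on average (the excess over the
nominal 5% reflects band-estimation error at n = 111). The per-metric rate
of any *single* realised model varies with SD ≈ 1.5 percentage points, so
calibration is checked as the expectation over independently built models
(25 models × 400 draws in the acceptance run), not on one realisation —
a single-model rate tests the cohort draw, not the method.

### QReport

JSON-first: the document of record holds raw unrounded values; HTML is a
pure view with display rounding (volumes to whole mm³, ratios and qT2 to
one decimal, matching the precision of published summary tables) and
deterministically regenerated figures (subject curve in black over the blue
normative band, posterior → anterior). Demographics are restricted to the
non-identifying set (age, gender, scan date, scanner, hospital).
Segmentation snapshots are the three orthogonal slices through each mask's
centroid voxel with the erosion-difference boundary overlaid. The exact
visual layout of a clinical QReport is not recoverable from prose
descriptions; this layout is a faithful-content redesign.

## Synthetic phantom

Each hippocampus is a tube around a cubic-spline "banana" centerline
(posterior→anterior, arching laterally and superiorly), circular
cross-section with a cosine-like taper toward both ends (end radius =
taper × base radius, default taper 0.5, base radius 5.5 mm, length ≈ 48 mm,
volume ≈ 3.3 mL), voxelised by distance to a densely sampled centerline
with flat end caps and reduced to its largest 6-connected component.
Circular rather than elliptical sections keep the analytic volume
∫πr(s)²ds an exact oracle; the curved centerline already makes the
principal-axis extraction non-trivial. Atrophy scales the radius by
√(atrophy factor), so volume is proportional to the factor up to
voxelisation error (≤3 percentage points at the default resolution). T2
elevation multiplies the baseline T2 uniformly, or as a Gaussian bump in
normalised arc position (SD = `focal_width`) for focal lesions.

Signal: echo_k = S0·exp(−TE_k/T2) plus additive Gaussian noise (default
σ = 10 at S0 = 1000, i.e. 1%). Additive Gaussian, not Rician: at phantom
SNR the two-point fit stays effectively unbiased (measured in-mask mean
bias ≈ 0.1% at 1% noise), which keeps fit-accuracy tests interpretable;
Rician magnitude noise is future work. The background is a single tissue
class (S0 800, T2 80 ms) inside an ellipsoidal head, zero signal outside —
the pipeline only reads inside masks, so richer anatomy adds nothing
testable. The T1-like volume exists solely for snapshot rendering.

Reference cohorts draw, per subject: a shared size factor (SD 8%, cancels
from ratios), per-side size factors (SD 4%), per-side T2 (SD 1.9 ms at
100 ms), and one mirrored centerline jitter (SD 0.8 mm, identical across
sides so geometry noise also cancels from ratios). The per-side SDs were
fixed so the healthy L:R ratio spread reproduces the published normative
bands: ratio SD ≈ √2·4% = 5.66% → volume band ≈ [88.9, 111.1]%, and
√2·1.9% = 2.69% → qT2 band ≈ [94.7, 105.3]%. All randomness flows from one
seed with a documented draw order.

What the phantom does **not** emulate: partial-volume voxels, anatomy
around the hippocampus, B1/stimulated-echo effects, Rician noise, scanner
drift, or segmentation error (masks are the generating geometry itself).
Passing tests therefore demonstrate correctness of the quantification
given masks and the signal model — not robustness to real segmentation or
acquisition artefacts.

## Reader-study battery

Ratings are 4-category nominal (normal / right / left / bilateral HS)
against a clinicopathological gold standard; the default simulated design
is 43 cases (23 normal, 9 right, 6 left, 5 bilateral) × 9 raters (3
experts, 3 trainees, 3 analysts) × 2 paired conditions (with/without
report).

- **Detection** collapses ratings to normal/abnormal: any abnormal category
  is a detection even if mislateralised (lateralisation is scored
  separately as exact-category accuracy over abnormal cases). Accuracy =
  100·(TP+TN)/(TP+TN+FP+FN).
- **Kappa** is unweighted 4-category Cohen's kappa, chance agreement from
  marginal products; κ = 1 whenever observed agreement is 1. Verbal bands:
  0.60–0.79 moderate, 0.80–0.90 strong (extended below/above in the same
  scale family). Group summaries are unweighted means of rater kappas.
- **McNemar** on paired correct/incorrect designations: exact two-sided
  binomial below 25 discordant pairs, continuity-corrected χ²₁ otherwise
  (the variant is a package decision; the test is usually named without
  one). b = c = 0 gives p = 1 by convention.
- **Paired t tests** across raters report d_z = mean(d)/SD(d) and Hedges'
  g_z = d_z·(1 − 3/(4·df − 1)); an average-SD classical d is also emitted
  because group-level d on summary SDs is common in print and can differ
  noticeably from d_z at small n. |d| > 0.8 is labelled large.
- **Reliability**: Cronbach's alpha and the two-way mixed-effects
  consistency ICC, single (MS_R−MS_E)/(MS_R+(k−1)MS_E) and average
  (MS_R−MS_E)/MS_R — the "single/average measures" vocabulary of standard
  statistical packages; the model name is stamped into output provenance.
  Categorical ratings are coded ordinally (normal=0, right=1, left=2,
  bilateral=3) for these indices; the coding is a convention and is
  documented rather than hidden.
- **Confidence ANOVA**: balanced repeated-measures (2 correctness × 2
  condition within raters) and mixed (2 condition × 2 scan-normality within
  × 3 experience groups between, on correctly diagnosed scans), by the
  standard balanced sums-of-squares decomposition with each within effect
  tested against its factor × subject(within-group) stratum and partial
  η² = SS_effect/(SS_effect+SS_error). Unbalanced or incomplete tables are
  rejected, never approximated — a paired reader study is balanced by
  design, and an empty cell (e.g. a rater with no incorrect assessments)
  makes the corresponding ANOVA undefined; the analyzer then reports it as
  absent with a note. No multiple-testing correction is applied.

The simulator draws detection with probability sensitivity (+δ with
report), exact lateralisation with probability λ (+δ), errors uniform over
the remaining abnormal categories, false positives at 1−specificity with a
uniform random category, and confidence from a clipped discretised Gaussian
whose mean depends on correctness and condition. Recovery: the analyzer
recovers a generating sensitivity of 0.875 to within Monte-Carlo error
over 200 replicate studies.

## Numerical and design choices

- One internal world convention (RAS+, voxel-centre, 0-based indices);
  inputs are reoriented on load. Grid equality tolerates 1e-5 on affine
  entries — header float noise, not misregistration.
- Normative statistics are computed on sorted values so model building is
  exactly permutation-invariant (float summation is not associative).
- The focal-localisation check places the lesion at arc 0.5, which is the
  shared closed edge of the two central bins of a 20-bin profile; either
  adjacent bin counts as the containing bin.
- Problem sizes in the automated checks — 100 randomised phantoms for
  conservation/localisation, 25×400 draws for flag-rate calibration, 200
  replicate studies for recovery — were sized so Monte-Carlo error is
  ≥3× smaller than the tolerance being checked.

## Known limitations

Two-echo fitting cannot separate fit failure modes (noise vs. flow vs.
artefact); the validity flag is binary. The principal-axis long axis can
differ from a template-defined axis for strongly hooked hippocampal heads.
The shipped normative model covers ratio metrics only. ANOVA requires
balance; missing-data designs need a mixed-model approach that is out of
scope. The rating simulator is parametric and case-exchangeable — it has no
per-case difficulty structure, so it cannot emulate case-driven rater
correlation.
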