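# Methods

This note documents the models, defaults and design decisions behind
`thymospec`, in the spirit of a statistical methods appendix.

## qPCR quantification

**Standard curves.** For each target (TEL, BG, TREC, KREC) the calibration
is an ordinary least-squares fit of Cq on log₁₀ of the known quantity,
requiring at least three distinct dilution points. The telomere assay's
reference ladder is eight 1:2 dilutions starting at 21 ng/well, ending at
21·2⁻⁷ = 0.1640625 ng; the duplex TREC/KREC ladders are decade dilutions
in copies. Efficiency is `100·(10^(−1/slope) − 1)`; a slope of
−1/log₁₀2 ≈ −3.3219 is perfect doubling (100 %). A fitted slope ≥ 0 is an
assay failure, not a warning. Note that a slope of −3.05 implies 112.8 %
efficiency; the module always reports the slope-derived value and does not
round it independently.

**Interpolation and QC.** Sample quantities are `10^((Cq − intercept)/slope)`;
values more than one log₁₀ outside the standards' range raise an
extrapolation warning. Replicate quality control operates on the
*interpolated quantities* (not Cq): CV = 100·sd/mean with the sample
(n−1) standard deviation, rejecting strictly above the 15 % threshold
(CV = 15.0 % passes, matching the "greater than" wording of the acceptance
rule). The replicate summary is the **median** of the interpolated
quantities — robust to a single aberrant well; the choice of median over
mean is a design decision, both being defensible. A rejected replicate
group yields a flagged-invalid T/S or an absent (None, never zero)
copies/ml value with a reason attached.

**Normalization.** TREC/KREC copies per reaction are scaled to copies per
ml of blood by `cells_per_ml / cells_per_reaction`, both explicit
configuration (defaults 2×10⁶ lymphocytes/ml and 1.25×10⁵ cell
equivalents per reaction). No-template controls amplifying below Cq 38
(configurable) abort the plate as contaminated.

## Spectratype analysis

**Normalization.** Within a subgroup, peak areas below 2 % of the subgroup
total (configurable) are zeroed as undetectable; the remainder is
renormalized to sum to 1. A subgroup whose total area falls below a small
floor is marked undetected and excluded from classification, perturbation
scoring and category denominators.

**Classification.** Decision order: (1) *mono/oligoclonal* if the top-1
area share ≥ 0.40 or top-2 share ≥ 0.60; (2) *restricted* if fewer than 7
detectable peaks; (3) *normal* if a least-squares discrete Gaussian
(amplitude, mean, width) fits the relative-area vector with R² ≥ 0.90,
otherwise *shifted*. Dominance is checked first so a 7-peak profile with
one towering peak is called oligoclonal rather than normal. The thresholds
(0.40 / 0.60 / 7 peaks / R² 0.90) are exposed in `ClassifierConfig`; none
of them has a canonical published value, so they are package defaults
chosen to realize the verbal definitions of the four categories. The
Gaussian score is computed by profiling out the amplitude analytically and
searching (mean, width) on a fine deterministic grid (mean step
1/8 ladder position, 48 geometric width steps) — deterministic,
vectorized, and accurate to well under the 0.90 decision margin for the
shapes that matter.

**Perturbation.** `D(p, r) = ½ Σ|pᵢ − rᵢ|·100` over the union of the two
ladders (absent positions count 0). This is the total-variation distance
scaled to [0, 100]: symmetric, zero iff equal, 100 on disjoint support,
and a metric (triangle inequality), which the tests verify against a
brute-force oracle. The reference is the per-subgroup mean of 12 healthy
controls drawn with a seeded generator from the HC pool; *all* HC subjects
(members included) are then scored against that mean to give the
per-subgroup HC perturbation mean and SD used for flagging. Flags are
strict: D must exceed mean + 2·SD (or + 3·SD). Whether the reference
members should be excluded from the flagging statistics is ambiguous in
practice; including them is the package's choice and is visible in the
`ReferenceRepertoire` contents. Global perturbation is the mean D over a
subject's detected subgroups, with the detected count reported.

**Summaries.** Category proportions are pooled over (subject × detected
subgroup) units per group; per-subject values (fraction of non-normal
subgroups, global perturbation) are reported alongside so subject-averaged
summaries can be derived. TRBV usage is each subgroup's share of a
subject's total area.

## Cohort statistics

Kruskal–Wallis H with tie correction (identical-value degenerate input
returns H = 0, p = 1). Dunn's pairwise z-tests use pooled mean ranks with
the tie-corrected variance; the adjustment is Bonferroni — the customary
"corrected" post-hoc in this workflow, recorded in the output. Post-hoc
tests run only when the omnibus p ≤ α (default 0.05) and more than two
groups are present; with exactly two groups the omnibus p is itself the
reported two-group p-value. IQRs are Q1–Q3 with linear-interpolation
quantiles. Demographic tables use Fisher's exact test (categorical) and
the unpaired t-test (continuous).

## Synthetic cohort generator

**What it emulates.** Three groups (21 pHIVy, 19 npHIVy, 40 HC) with
clinical margins matching published cohort descriptives (age medians
27/27/28 years; CD4 medians ≈ 800–850/µl in all groups; CD4/CD8 ratio
medians 0.8/1.2/2.0); group-level clonality-class mixes whose reported
anchors are normal 16.8/18.8/27.5 %, restricted 49.5 % (pHIVy) vs 35.5 %
(HC) and mono/oligoclonal 11.4 % (npHIVy) vs 2.9 % (HC), with the
unreported shares completed by complement; lower telomere T/S in the HIV
groups (defaults 0.85/0.87 vs 1.05, between-subject SD 0.18 — levels are
not published, these are realistic relative values); TREC/KREC levels
identical across groups (3.6 ± 0.45 and 3.8 ± 0.45 log₁₀ copies/ml),
matching the non-significant group comparison the pipeline should
reproduce; and configured Pearson correlations (TREC–CD4 r = 0.75,
T/S–CD4 r = 0.75, perturbation–CD4/CD8 r = −0.81, all within pHIVy).

**Copula.** Within each group a subject's latent variables are jointly
Gaussian; each margin is an explicit transform (lognormal for counts and
ratios matched to median/IQR, normal for percentages and T/S, 10^normal
for excision circles). Because nonlinear margins attenuate Pearson
correlation, each configured target is mapped to its latent correlation by
bisection against the realized Pearson r on a fixed 200 000-point
quadrature sample; the assembled latent matrix must be positive definite
or configuration fails naming the offending pairs. Two default couplings
(TREC–T/S r = 0.70 and ratio–CD4 r = 0.18) exist to keep the default
target set jointly feasible and are biologically sensible in their own
right. CD8 counts are derived as CD4/ratio so the ratio invariant holds
exactly; consequently CD8 medians are implied rather than matched. The
perturbation target r = −0.81 is induced on the *latent severity*
variable; the measured global perturbation correlates with severity only
through noise scaling, so the measured-space correlation is attenuated —
a documented limitation.

**Seeding.** Every subject's draws derive from
`SeedSequence(seed, spawn_key=(group, subject, stream))`: adding subjects
or groups never changes earlier subjects' data, and a fixed seed gives
byte-identical output files.

**Spectratype archetypes.** Class labels are drawn i.i.d. per (subject,
subgroup) from the group mix, so pooled proportions are unbiased. Profiles
realize the labels on an 8-position, 3-nt ladder with per-subgroup size
offsets: *normal* is a discrete Gaussian (width 1.7–2.2 positions);
*shifted* a well-separated bimodal mixture; *restricted* 5–6 peaks blended
toward uniform so no peak approaches the dominance thresholds;
*mono/oligoclonal* one dominant peak (55–80 % share) or two adjacent-ish
peaks (70–82 % combined). Multiplicative lognormal noise (σ = 0.08,
scaled by subject severity, clipped to [0.5, 2]) is applied before
renormalization. These archetypes are deliberately well separated: the
classifier recovers the generated labels with ≥ 99 % accuracy at the
default separation, with residual confusion confined to normal↔shifted.
Real spectratypes are messier — partially overlapping categories,
instrument baseline artefacts, off-ladder peaks — so passing recovery
tests demonstrates correctness of the arithmetic and decision rules, not
classifier performance on real capillary-electrophoresis data.

**qPCR plates.** Standards at the ladders above, samples in triplicate,
one no-template control per target; Cq = intercept + slope·log₁₀(q) +
N(0, σ) with σ = 0.05 cycles by default (≈ 4 % quantity CV per well, so
triplicates comfortably pass the 15 % QC). Noiseless plates round-trip all
quantities exactly, which the tests pin to 1e-9.

**What the generator does not model.** Raw electropherograms, sequencing
reads, longitudinal trajectories, plate-position effects, inter-run drift
beyond a single noise term, and any within-subject coupling between the
qPCR assays beyond the copula.

## Problem sizes and numerical notes

The cohort-level recovery suite runs the full pipeline on 100 default
cohorts (80 subjects × 23 subgroups each), a few minutes on one CPU; the
correlation recovery check uses n = 2000 subjects per draw. Pearson r
estimated on the heavy-tailed TREC margin at n = 2000 has a sampling SD of
about 0.026, so the acceptance script reports the median over 9
independent cohorts. Degenerate inputs are defined, not special-cased
away: identical groups give H = 0/p = 1; zero-variance correlation input
is flagged undefined; an all-zero subgroup is undetected rather than a
NaN distribution; flat profiles get a Gaussian score of 0.

## Known limitations

- Measured perturbation correlations are attenuated relative to the latent
  targets (see above); only the latent-variable correlations are
  calibrated.
- The 23-subgroup TRBV vocabulary is fixed; assays resolving families at
  finer grain (or including ORF subgroups) need a different list.
- The classifier thresholds are conventions, not estimates; on real data
  they should be tuned against expert-labelled profiles.
- Multi-run consolidation of qPCR samples (inter-assay drift) is reduced
  to a single-run model with one noise term.
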