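# Methods

This note documents the models, defaults, and numerical conventions
behind `episcreen`, and what the synthetic-data generator does and does
not emulate.

## Coordinate and boundary conventions

All genomic intervals are 0-based half-open. TSS-relative assay
coordinates (e.g. an amplicon at −3617..−3352 with measured CpGs at
−3524..−3439) are metadata converted strand-aware at the I/O boundary,
never recomputed against a genome build. "Within 5 kb of the island"
means the motif interval is contained in
`[island.start − flank, island.end + flank)`; a hit starting exactly at
`island.end + flank` is outside (half-open). Distances between intervals
are gap-wise: 0 when they overlap or touch.

## CpG island detection

A window of 200 bp (1-bp step) qualifies when it is N-free, has
G+C ≥ 0.5, and CpG observed/expected ≥ 0.6, with
O/E = (#CpG · L)/(#C · #G) and O/E defined as 0 when a window lacks C
or G. Qualifying windows that overlap or are adjacent are merged; each
merged region is then reduced to its largest sub-interval (leftmost on
ties) that itself satisfies all criteria at length ≥ 200 bp. The search
runs candidate lengths in descending order, so the common case — the
whole merged region qualifies — exits immediately; reported islands are
disjoint and sorted. All five criteria are configuration keys; the
defaults are the classic Gardiner–Garden–Frommer values. Windows
containing N never qualify, and degenerate inputs (sequence shorter
than the window) return an empty list rather than an error.

The detector is vectorized over cumulative base counts; the test suite
holds it equal to an exhaustive per-window enumeration with naive string
counting on sequences up to 5 kb across 100 random seeds.

## GAS motif scanning

The default motif is the GAS consensus `TTC N{s} GAA` with spacer
s = 3 (a configurable range 2–4 is supported). The reverse complement
of `TTC N{s} GAA` is again `TTC N{s} GAA` for every spacer, so each
consensus hit matches on both strands; identical intervals from the two
strand scans are collapsed and recorded as strand `both`. Overlapping
occurrences are all reported; N never matches. A position-weight-matrix
mode (log2-odds against a uniform background, per-strand hits) exists
but is off by default, since the screen is defined on the consensus.

## The screen

A gene passes when all configured criteria hold:

1. a CpG island overlaps its strand-aware promoter window
   (1000 bp upstream, 500 bp downstream of the TSS by default); when
   several overlap, the island nearest the TSS (gap-wise, then leftmost)
   is assigned;
2. at least one motif hit lies within `flank` (default 5000 bp) of the
   assigned island's boundaries;
3. Pearson correlation of the gene's log2(RPKM+1) with the regulator's
   across all samples is ≤ −0.3 with BH-adjusted q ≤ 0.1 (BH runs over
   every gene with a computable correlation);
4. mean log2(RPKM+1) is lower in tumor than in normal columns
   (direction only; switchable off).

Passing genes are ranked by ascending correlation, then nearest-site
distance, then gene id — an invented but deterministic rule. The
correlation threshold and q are deliberately soft defaults: the screen's
behavior comes from the filter structure, and both are configuration
keys. Tightening any single threshold can only remove passing genes
(verified as a property test).

## Expression analytics

RPKM uses the column sum of counts as the library size; no external
mapped-read totals exist at the matrix level. Tests and correlations
default to log2(RPKM + 1) — a pseudocount of 1 RPKM — because t and
Pearson statistics behave better on logs for overdispersed counts; the
raw scale is a flag. The tumor/normal comparison defaults to the
unpaired pooled-variance t-test, with a paired mode available for
matched-tissue designs. Degenerate zero-variance comparisons return
p = 1 (equal means) or p = 0 by convention. Comparative-Ct assumes
perfect doubling (efficiency 2): ΔCt = target − reference,
ΔΔCt = ΔCt − mean ΔCt of the calibrator group, relative expression
2^−ΔΔCt, so the calibrator's geometric mean is exactly 1. ChIP
enrichment is the ΔΔCt-style fold of (IP − input) at the test locus
over a control locus.

## Methylation quantification

Per-CpG methylation percent is 100 · C/(C + T) from the C- and
T-dispensation intensities at that CpG; a CpG with C + T = 0 raises an
error naming the failed dispensation. The per-sample value is the
arithmetic mean over the assay's CpGs (11 by default). Quantification is
scale-invariant in the intensities. Dichotomization sends values
strictly above the cutoff high and ties low; `"median"` uses the sample
median. The threshold that defines a patient as "methylated" for
prevalence statistics is a required parameter with no default, and is
always echoed in reports, because the prevalence call and the survival
split need not share a cutoff.

## Clinical statistics

Group comparisons use the pooled-variance (Student) unpaired t-test.
Printed "mean ± value (n)" summaries can be fed directly; the ± value
is interpreted as an SEM by default (sd = value·√n) with an `"sd"` flag
for the literal reading. The SEM default was chosen because it is the
interpretation under which published tables of this layout reproduce
their own printed p-values — verified here by an independent oracle that
constructs raw samples matching each summary exactly and t-tests them
with scipy. Kaplan–Meier estimation and the log-rank test are delegated
to `lifelines` behind this module's interface; the suite pins both to
hand-computed risk-table oracles on cohorts of ≤ 20 patients. The
median survival is the first event time with S(t) ≤ 0.5, without
interpolation, and is absent when the curve never reaches 0.5. A
log-rank comparison with no events in either group returns p = 1 by
convention. Cox regression is out of scope.

## Synthetic-data generator

**Genome.** One chromosome (3 Mb default) of IID background at 40% GC,
CpG-thinned to O/E ≈ 0.25 to mimic the CpG depletion of bulk genomic
DNA — this keeps chance islands out of non-target promoters. Genes
(200) sit at even spacing on alternating strands; gene `G001` is the
regulator. Each of the 10 target genes receives a 300-bp island segment
(60% GC, O/E 0.8, rejection-sampled until it meets detector-grade
criteria) covering its TSS, plus one `TTCNNNGAA` insertion 50 bp to
~4.5 kb downstream of the island. Chance GAS motifs (spacers 2–4)
within the flank zone of non-target promoters are destroyed by mutating
the TTC half-site's C, which breaks the match on both strands; the
planted truth is re-scanned after assembly and generation fails loudly
if a recorded motif was damaged. A sizing error is raised when the
chromosome cannot host the requested genes with disjoint feature zones.

**Expression.** Counts are gamma-Poisson (negative binomial,
var = μ + αμ² with α = 0.05) on log-linear means. The regulator runs
1 log2 unit higher in tumors with 1.0 log2 SD of biological noise.
Each target shares the regulator's latent residual with coefficients
solved in closed form so that the **marginal** correlation across all
2n samples equals the requested ρ (−0.6 default) while the tumor −
normal mean difference equals the requested log2FC (−2 default), under
a total target SD of 1.3 log2 units. Non-target genes are independent
noise around uniform baselines. Count noise attenuates the realized
log-RPKM correlation a few percent below |ρ|; at the study's n = 23
pairs this stays well inside the Fisher-z sampling interval. RPKM is
compositional: in matrices of only a handful of genes the regulator's
own library share induces spurious negative correlation, so simulated
matrices should be genome-scale (~200 genes), where the effect is
negligible — the null configuration then calibrates the correlation
test's type-I error at nominal α.

**Pyrograms.** Each CpG's C and T intensities are
(fraction, 1 − fraction) plus Gaussian noise (SD 0.02 default)
truncated at zero, with unit-intensity reference dispensations
interleaved. Methylation levels for a cohort come from a planted
two-component mixture: exactly 65% of patients (rounded) draw uniformly
from 40–80% and the rest from 5–30%, so prevalence at a 35% threshold
is exact by construction.

**Clinical.** Survival is exponential; patients above the cohort median
methylation (ties low) carry hazard_ratio × the baseline hazard, with
the baseline calibrated so the low group's median OS is 27.1 months.
Censoring is independent exponential at ≈ 20%. Covariates (age, sex,
stage, grade, H. pylori) follow configurable distributions shaped like
a 60-patient gastric cohort and are independent of methylation by
default, so covariate comparisons are null.

**What is not emulated.** No read-level data, sequencing error,
alignment, copy number, mutation, batch structure, or within-patient
tumor/normal correlation beyond the shared latent factor; survival has
no covariate effects, non-proportional hazards, or cure fraction.
Passing tests on these data show the pipeline's statistical machinery
is correct and calibrated under its own generative assumptions, not
that real cohorts satisfy those assumptions.

## Determinism and problem sizes

Every operation draws from one seeded `numpy` generator; distinct
stages derive distinct streams from the single run seed, and a fixed
seed reproduces byte-identical output files. The pipeline re-runs its
stages unconditionally — at these problem sizes a full run takes
seconds, so stage caching would add complexity without benefit; the
manifest records input/output SHA-256 hashes so reruns can be verified
identical.

Simulation sizes used by the test suite and acceptance script: 20
planted genomes for screen sensitivity/FDR; 500
replicates for type-I calibration and log-rank power; 1000 samples for
pyrosequencing recovery; 100 random sequences for the island-detector
oracle. These sizes put Monte-Carlo standard errors well inside the
asserted bands.

## Known limitations

- The maximal-qualifying-subinterval reduction is quadratic in the
  merged-region length in the worst case; fine at island scale, and the
  descending-length scan exits immediately in the common case.
- The GAS consensus carries no affinity model; the PWM mode exists but
  ships without a default matrix.
- Screen sensitivity at the default conditions is bound by the BH step
  on 200 genes: the weakest planted targets can land just above
  q = 0.1, which is why measured sensitivity sits near 0.92 rather
  than 1.
- `methylated_fraction` treats the calling threshold as external; it
  makes no attempt to estimate a mixture from data.
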