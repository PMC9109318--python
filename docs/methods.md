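# Methods

## Scar scores from allele-specific segments

The unit of input is an allele-specific copy-number segment: a genomic
interval with a total copy number (tCN) and a minor-allele copy number
(mCN), as emitted by allele-specific callers such as PureCN downstream of
a targeted panel with genome-wide SNP backbone. Coordinates are 1-based
inclusive (the SEG convention); the reader converts 0-based half-open
input on request. Profiles need not tile the genome — uncovered gaps are
legal, and what a gap means is decided by the scoring parameters below,
not by the reader.

Before any counting, abutting equal-state segments are fused
(`merge_equal_state` with zero gap). This makes all three scores invariant
to input ordering and to splitting a segment into equal-state pieces, so
upstream segmentations that emit redundant breakpoints cannot inflate
counts.

**LOH** counts segments with mCN = 0, tCN > 0 and length ≥ 15 Mb that do
not cover the whole chromosome. "Whole chromosome" is operationalized as
covering at least 90% of the chromosome length (`whole_chrom_fraction`,
configurable): panel-derived segments rarely reach literal base 1 or the
final base, and whole-chromosome LOH is an aneuploidy event rather than a
recombination scar.

**TAI** counts allelic-imbalance segments (mCN ≠ tCN − mCN) that reach a
telomeric end. Covered territory never reaches the telomere repeats, so a
segment "reaches" the p (q) telomere iff it is the first (last) segment
of its chromosome — the standard proxy. Segments spanning the centromere
are excluded by default (`tai_exclude_centromere_crossing`), following the
signature's primary definition; a minimum-length filter exists and
defaults to 0.

**LST** counts breakpoints between adjacent segments that both measure at
least 10 Mb and are separated by at most 3 Mb, after smoothing: segments
shorter than 3 Mb are iteratively removed (shortest first, leftmost on
ties) and newly adjacent equal states are re-fused across gaps of up to
3 Mb. A breakpoint requires an actual change in (tCN, mCN). Counting is
per-arm by default — pairs straddling the centromere, including pairs
involving a centromere-spanning segment, are not counted — with both the
smoothing scale and per-arm behaviour exposed as configuration, since
pipelines differ on both.

The **HRD score** is the sum LOH + TAI + LST, and a sample is HRD-positive
when the score is **greater than or equal to** the threshold (inclusive
comparison; default 38). Sex chromosomes are carried through the data
model but excluded from scoring by default, because allele-specific copy
number on X/Y depends on sex and the scar definitions presume two
parental haplotypes.

## BRCA and HRR-gene classification

A variant is pathogenic if truncating (nonsense or frameshift) or
clinically asserted pathogenic/likely-pathogenic; gene-level log2 copy
ratios discretize at ±1 (amplification/deletion) with homozygous deletion
at ≤ −2 (configurable — the ±1 cutoff defines single-copy events, and
biallelic loss needs a stronger signal). A gene is deficient when it has
two distinct pathogenic alleles, one pathogenic allele plus a deletion, a
homozygous deletion, or a large-rearrangement flag. Panel data carry no
phase, so two distinct pathogenic alleles in one gene are assumed in
trans; distinctness is resolved by `allele_id`, so a germline variant
re-detected somatically counts once. Samples split three ways: deficient;
monoallelic pathogenic (one hit, no second); intact (no pathogenic
alteration). Monoallelic and intact together form the non-deficient
group used in score comparisons. The same deficiency logic applied to a
25-gene HRR panel (shipped list is provisional and user-overridable)
yields the HRR-deficiency flag for BRCA-intact samples.

## Threshold calibration

Because HRD scores are discrete, the sensitivity for detecting
BRCA-deficient samples is a step function of the cutoff, and a whole band
of cutoffs attains the same sensitivity level. `candidate_cutoffs`
defaults to the *tightest* reading: the cutoffs attaining the smallest
sensitivity level still ≥ 95%, a band bounded on both sides (an
`at_least` mode returning every qualifying cutoff — a downward-closed
set, since sensitivity is non-increasing in the cutoff — is also
provided). `select_cutoff` takes the band's median, with the **lower**
median for even-sized bands. The survival route fits, for each integer
cutoff in 35–45, a univariate Cox proportional-hazards model of PFS on
the dichotomized score and reports the full scan plus the cutoff with the
smallest p-value; ties in day-granularity PFS use Efron's method (the
lifelines default). Cutoffs leaving fewer than two samples in an arm are
skipped with a warning.

## Cohort statistics

Group score comparisons use the two-sided Wilcoxon rank-sum test; PFS by
group uses Kaplan–Meier medians (reported as not-reached when the curve
never crosses 0.5) with the log-rank test; the multivariate Cox model
dummy-codes stage (IV vs III) and residual tumour (R1, R2 vs R0)
alongside HRD status. Alteration enrichment applies the two-sided
Fisher's exact test to every binary alteration column with overall
frequency above 5%, returning those with p ≤ 0.05 and their direction;
mutation, copy loss and amplification of one gene are distinct columns.
No multiple-testing correction is applied by default (raw p ≤ 0.05 is the
reported criterion); Benjamini–Hochberg is available as an option.
Cross-pipeline concordance uses Pearson's r on scores and unweighted
Cohen's kappa on binary calls.

## Simulator

`simulate_profile` starts from a balanced diploid genome — one (2,1)
segment per autosome on the bundled hg19 build — and plants events whose
scored counts are *exactly* the requested counts:

* LOH: interstitial (1,0) segments, length uniform 15–40 Mb;
* TAI: terminal (3,1) (8–20 Mb) or (2,0) (8–14 Mb, kept below the LOH
  length floor) segments that never span the centromere;
* LST: abutting pairs of 10–13 Mb segments with different states inside
  one arm.

Exactness comes from isolation, not luck: every event is separated from
everything else by a ≥ 5 Mb uncovered gap, wider than the 3 Mb LST
gap/smoothing scale, so events can neither fuse nor create unplanned
breakpoints; remaining territory is filled with balanced (2,1) filler
that also keeps 5 Mb clear of events, and chromosome tips hold balanced
filler unless a TAI event owns them. Noise events (interstitial LOH
below 15 Mb, interior imbalance, breakpoints with sub-10 Mb flanks, all
≥ 4 Mb so smoothing leaves them) are sub-threshold by construction. The
planted-truth equality is verified by test, not assumed. Events that
cannot be placed retry at their minimum size before raising a placement
error; genome territory caps the placeable score at 30 LOH + 8 TAI + 28
LST = 66, below the highest scores seen in real tumours — a deliberate
trade against the isolation gaps that make recovery exact.

`simulate_cohort` layers a clinical model on top. Each sample is
BRCA-deficient with probability `frac_brca_deficient`; deficient samples
are HRD-high except for a pinned ⌊5%⌋ of escapees (matching the
discovery-cohort structure in every replicate, not merely in
expectation), and escapees draw near-threshold totals just below the
margin — deficient tumours that miss the positive class still carry
partial scarring. HRD-high totals are uniform on [threshold + margin,
66], HRD-low on [0, threshold − margin); the margin (default 10) keeps
truth unambiguous, and margin 0 gives the continuous score spread needed
to localize a cutoff by survival scanning. PFS is exponential — hazard
`baseline_hazard` (default ln 2/343 per day, a 343-day median) times
`hr_hrd` (default 0.47) for HRD-positive samples — under independent
uniform censoring whose horizon is solved numerically so the realized
censoring fraction matches `censor_rate` against the cohort's mixture of
event-time distributions. Platinum sensitivity is Bernoulli with
probability 0.82 (positive) / 0.57 (negative); stage and residual tumour
follow typical advanced-ovarian frequencies (90% III; 50/43/7% R0/R1/R2).
The alteration matrix plants one column enriched in positives
(`TP53_mutation`, 95% vs 60%), one in negatives (`CCNE1_amplification`,
8% vs 40%), and frequency-matched nulls; BRCA variant tables are emitted
consistent with each sample's status so the classifier can be exercised
end to end. With `generate_profiles=False` totals are taken from the
planted counts directly — justified by the planted-truth equality — which
makes replicate studies (null calibration, threshold recovery) cheap.

What the simulator does *not* emulate: purity/ploidy estimation error,
subclonal copy number, noisy tCN/mCN calls, overlapping or interacting
scars, non-exponential survival, and informative censoring. Passing tests
therefore demonstrate correctness of the counting rules, the calibration
logic and the statistical plumbing under clean segmentations — not
robustness to upstream caller noise.

## Numerical and design notes

* Test problem sizes: oracle equivalence uses 200 random profiles per
  component; planted-truth recovery 500 parameter draws; survival
  recovery one 500-sample cohort plus 200 null replicates of 120 samples;
  the Fisher oracle enumerates every 2×2 table with total ≤ 60.
* The exhaustive Fisher check compares against hypergeometric enumeration
  with the same relative-tolerance tie guard (1 + 1e-13) used for
  selecting tables no more probable than the observed one.
* Degenerate inputs fail loudly: unknown chromosomes, overlapping
  segments, mCN exceeding the major allele count, constant Cox
  covariates, single-group log-rank, zero-variance correlation, and
  no-deficient-sample sensitivity are all errors, never silent results.
* The bundled hg19 file carries UCSC chromosome lengths with centromere
  intervals from the acen cytoband annotation; other assemblies inject
  via a four-column TSV.
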