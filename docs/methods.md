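# Methods

## Problem and scope

`isomirkit` analyzes small-RNA sequencing tags against pre-miRNA hairpin
references to detect and quantify isomiRs — sequence variants of canonical
mature miRNAs arising from shifted Drosha/Dicer cleavage, nucleotide
substitutions, or 3' non-templated additions (NTA). It implements the full
chain from raw reads to cohort-level biology: alignment, isomiR
classification and naming, normalized quantification with a noise floor,
robustness filtering, and three downstream screens (arm switching,
AGO2-cleaved pre-miRNA candidates, paired-condition ablation).

Alignment is deliberately restricted to hairpin references rather than a
genome: mature miRNAs are too short to place uniquely genome-wide once
mismatches are allowed, and the hairpin set is the biologically meaningful
search space.

## Alignment model

Placements are gapless Hamming matches with at most `max_sub = 2`
substitutions, no insertions or deletions, and a minimum aligned length of
`min_len = 20` nt (specificity collapses below that on ~22-nt molecules).
Two strategies are provided:

* **Recursive mapping.** The tag is tried at full length; while nothing
  places, `trim_step = 1` base is removed from the 3' end and the scan is
  retried, down to `min_len`. The first (longest) successful length wins.
  This maximizes sensitivity but leaves the true 3' end unknown, so it is
  used for expression quantification and decoy scanning, not for end-site
  isomiR calls. Trimming is 3'-only because base quality decays toward the
  3' end on short-read platforms.
* **Adaptor-trimmed mapping.** The 3' sequencing adaptor is located
  (5'-most position where an adaptor prefix matches the read with overlap
  ≥ 5 and ≤ 10% mismatches) and stripped, fixing the exact insert end. The
  insert is then placed in a single pass at full length after NTA peeling.
  Reads without a recognizable adaptor are "unusable by strategy" — they
  may still map recursively.

**NTA peeling.** For an exact-ended insert, all splits into a templated
core (≥ `min_len`) plus a 3' suffix of 0..`nta_max = 5` bases are
considered. A non-empty suffix is a valid NTA only if every suffix base
either falls past the hairpin 3' end or mismatches the template there. The
winning split minimizes (substitution count, suffix length): a fully
templated reading beats an NTA reading at equal substitution cost, and a
terminal mismatch is preferred as an NTA when that saves a substitution.
This tie-break makes a lone 3'-terminal mismatch read as a 1-nt NTA — an
inherent ambiguity of exact-end data that is documented rather than hidden
(the synthetic generator therefore never places a designed substitution on
the final base).

**Multi-mapping.** Equal-best placements (minimal substitutions at the
chosen length) are all retained with fractional weight 1/k, ordered by
(hairpin id, start). This conserves total tag mass through every
downstream matrix; no duplication, no discard.

## IsomiR features, categories, nomenclature

Each placement is assigned to the mature annotation (5p or 3p) whose span
it overlaps most (ties favor 5p; zero overlap with both arms — e.g. loop
placements — is tracked separately as "orphan-side" mass). Relative to
that annotation the tag is summarized as (Δstart, Δend, substitutions,
NTA), and classified into exactly one of seven mutually exclusive
categories:

| Δstart | Δend | subs | NTA | category |
|---|---|---|---|---|
| 0 | 0 | 0 | 0 | canonical |
| ≠0 | 0 | 0 | 0 | start_only |
| 0 | ≠0 | 0 | 0 | end_only |
| 0 | 0 | >0 | 0 | substitution_only |
| d≠0 | d | 0 | 0 | shifted (length preserved) |
| 0 | 0 | 0 | >0 | nta3 |
| anything else | | | | mixed |

The `nta3` class requires a canonical templated core; NTA on a variant
core is `mixed`, which preserves mutual exclusivity.

Names follow `<arm>|{<label>}|<start>_<end>|<modifiers>` with 1-based
inclusive hairpin coordinates of the templated span, label `isomiR` for
any non-canonical tag, substitution modifiers `sub.<pos>.<ref>><alt>` and
NTA modifiers `add.<pos>.<nt>` whose positions continue hairpin numbering
beyond the span. Canonical output is unspaced (`G>A`); the spaced dialect
(`G > A`) is accepted on parse. Parsing validates coordinate order and
modifier positions, and `parse(render(x)) == x` is property-tested.

## Quantification

Counts are (multiplicity × weight) mass per isomiR name per sample.
Expression is tags per million (tpm) of the effective library size
N·f, where f is the trimmed-mean-of-M-values (TMM) scaling factor
computed against a reference sample (the one whose upper-quartile count
fraction is closest to the cohort mean). Over features positive in both
sample and reference: M = log2 of the normalized count ratio, A = the
mean log abundance; the top/bottom 30% of M and 5% of A are jointly
discarded and f = 2 to the precision-weighted mean of the surviving M
values, with inverse delta-method-variance weights; factors are anchored
to geometric mean 1. Samples sharing fewer than 20 positive features with the reference fall
back to f = 1 with a warning. These internals follow the published TMM
defaults.

**Noise floor.** Cross-species decoy matures — sequences that cannot be
genuinely present — are aligned with the same parameters; any decoy found
within the substitution budget of a genuine target mature is dropped
first. The floor is the maximum per-decoy tpm over samples, rounded up to
an integer (the most conservative reading; a quantile rule would also be
defensible and the value is configurable). With no decoy hits the default
floor of 10 tpm applies. At desk-scale library depths the tpm quantum of a
single read is large (1 read in a 4,000-tag library ≈ 250 tpm), so
decoy-derived floors are only meaningful at realistic depths; the filter
tests therefore exercise the ceiling arithmetic on constructed fixtures.

**Robustness filters.** A feature is retained iff (i) some tissue shows it
at ≥ `min_tpm` (default 10) in *every* one of its samples, (ii) it is
detected (tpm > 0) in samples spanning ≥ 2 distinct library-prep kits, and
(iii) optionally it is not an orphan (an isomiR whose arm's canonical form
is detected in no sample — a mis-annotation signature). "Present" (tissue
rule, thresholded) and "detected" (kit rule, any evidence) are split
deliberately. Orphan flagging happens on the thresholded detection table
before filtering.

## Cohort analyses

**Positional profiles** accumulate tag mass per hairpin position and base
(the *tag* base, so substitutions are visible) plus beyond-end NTA bins,
with per-arm histograms of 5' starts and templated 3' ends; these are the
inputs for sequence-logo style displays and the ac-pre screen.

**Arm switching.** Per (hairpin, tissue), arm totals are the sum of
feature tpm on each arm averaged over the tissue's samples (the
aggregation had to be chosen; the mean is used). A hairpin is assessable
when ≥ 2 tissues have both arms at or above the noise floor, and switched
when its dominant arm is not constant across those tissues. Eligibility is
evaluated per tissue.

**ac-pre-miRNA screen.** Hairpins matured by AGO2 cleavage plus 3'
exonucleolytic trimming (the miR-451 route) show: a highly consistent
mature 5' end, a near-silent opposite arm, and a substantial trail of
templated 3' extensions. These qualitative characteristics are formalized
as: modal-5'-start fraction ≥ 0.9 of dominant-arm mass; opposite-arm
maximum tpm below the noise floor; and ≥ 10% of dominant-arm mass ending
≥ 2 nt past the canonical 3' end over ≥ 3 distinct end positions. All
thresholds are configurable. Both arms are screened as the potential
dominant arm; evaluation is restricted to tissues whose samples span ≥ 2
prep kits. Because the mature product of this pathway keeps its 5' end
fixed while the 3' end carries the trimming intermediates, the screen keys
on 5'-start consistency plus the 3'-extension trail.

**Ablation testing.** Candidates are validated against a paired wild-type
/ AGO2-inactive comparison. The deeper library is resampled without
replacement to the shallower depth (multivariate hypergeometric, fixed
seed, default 42). The group test is a 2×2 Pearson chi-square (no
continuity correction, 1 df) of candidate vs non-candidate mass across
conditions; the 2×2 construction is candidate-derived mass against all
other mapped mass. Per candidate: `complete_ablation` (no canonical mass
left in the mutant), `strong_reduction` (canonical reduction > 80%),
`isomiR_support` (arm isomiR mass in the mutant < 80% of wild type), else
`unsupported`.

## Synthetic data

The generator's defaults define the standard study conditions: 20 random
hairpins (built as 5' flank + 5p mature + loop ≥ 12 nt + 3p mature + 3'
flank, lengths ~60–80 nt; matures 20–23 nt), a category mixture dominated
by canonical tags (50%) with end-site variants the largest isomiR class
(20%), per-base substitution error 0.005, universal read-through into the
3' adaptor (miRNA inserts are much shorter than the read length), decoy
reads at 0.1%, and a cohort of three tissues × two prep kits at 4,000
reads per sample. Designed effects: two arm-switch hairpins (dominance
flips in one tissue), one ac-pre-like hairpin (uniform 5' start, silent 3p
arm, 25% of mass extending 2–8 nt past the canonical end), and one orphan
3p arm that only ever emits a +1 start-shift isomiR.

Indels are not simulated: the alignment model is substitution-only, and
short-read substitution error dominates on the platforms this model
targets. NTA bases are drawn to mismatch the template so truth categories
are unambiguous, and designed substitutions avoid the 3'-terminal base
(see NTA tie-break above). Every emitted variant is verified to have a
unique best placement across all hairpins before emission; decoys are
verified (exhaustively, including all recursive-trim prefixes) to place
nowhere on the target hairpins within the substitution budget.

What the generator does **not** emulate: RNA secondary structure,
ligation/sequence bias of library chemistry, color-space error profiles,
indels, and realistic (hundreds of millions of tags) depths. Passing
end-to-end tests therefore demonstrates correctness of the algorithms
under the stated error model, not robustness to every artifact of real
libraries.

## Numerical and design choices

* Coordinates are 1-based inclusive and hairpin-relative everywhere.
* U→T normalization on input; internal alphabet is DNA.
* Arm of a mature annotation: midpoint of its span vs hairpin midpoint;
  an exactly central midpoint counts as 5p (logged).
* Multiple occurrences of a mature in its hairpin: the 5'-most span is
  used, with a warning.
* Fractional multi-map weights are kept as reals end to end; nothing is
  rounded before tpm.
* TMM trimming uses rank bounds (floor(n·trim)+1 .. n+1−that) on both M
  and A; ties in ranks are averaged.
* The 19-nt printed worked example of the nomenclature (span 62–80) sits
  below the default 20-nt alignment floor; reproducing it lowers the floor
  to 19 for that single alignment, which does not affect the coordinate
  conventions being checked.
* Problem sizes in the test suite (cohorts of 4–6 samples at 250–800 reads,
  one 20,000-read sample for mixture recovery, 1,000 oracle alignment
  pairs, 10,000 nomenclature round trips) were chosen so the whole suite
  runs in well under a minute while leaving the statistical checks
  well-powered.

## Known limitations

* 5' non-templated additions are not modeled (treated as start variation).
* Indel-bearing isomiRs are invisible to the substitution-only aligner.
* The decoy noise floor is depth-sensitive at small library sizes (see
  above).
* Genome-relative annotation coordinates are not lifted over; only
  hairpin-relative annotations are accepted.
* The ac-pre thresholds are a formalization of qualitative criteria;
  sensitivity to their values should be explored per dataset.
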