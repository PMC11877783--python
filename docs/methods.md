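# Methods

## Problem setting

Each patient contributes up to four specimens: blood (germline control),
pathologically tumor-free SVZ tissue, the primary tumor, and — after gross
total resection and relapse — the recurrent tumor, all sequenced with a deep
targeted panel (the package's depth default of 1063x reflects a typical
median for such panels). The analysis decides, per patient, whether the
recurrence is genetically continuous with the dominant primary clone or
instead descends from an early progenitor shared with the SVZ.

## Presence model

Observed alt counts at a true-negative site follow Binomial(n, e) with a
uniform per-base miscall fraction e (default 1e-3, a standard hybrid-capture
noise floor; position-specific error, strand bias and mapping artifacts are
upstream-caller territory and out of scope). A call is:

- PRESENT: alt >= min_alt_reads (3) and the one-sided noise tail p-value
  <= alpha (1e-3). The joint threshold is k*(n), the smallest alt count
  passing both.
- ABSENT: not PRESENT, and detection power P(X >= k* | Bin(n, vaf_detect))
  >= power_floor (0.9) at vaf_detect = 0.02. This is the "absence requires
  power" principle: at 30x the study cannot exclude a 2% clone, so the call
  is INDETERMINATE instead.
- INDETERMINATE otherwise.

The three states are exclusive and exhaustive; PRESENT is monotone in alt
count at fixed depth. Detection power is only piecewise-monotone in depth:
k*(n) is integer-valued and steps up at certain depths (with the defaults,
from 3 to 4 near n ≈ 185), where power at low VAF dips before resuming its
climb. Tests therefore assert monotonicity on a depth-doubling grid, where
the depth gain always dominates the threshold jump.

No multiple-testing correction is applied across variants: the intended
input is a small curated panel with per-call thresholds, not genome-wide
discovery. Germline exclusion applies the same PRESENT test to blood.

## Categories and patient labels

Categories are a pure function of the (SVZ, primary, recurrent) presence
triple, implemented by completion enumeration over INDETERMINATE slots (see
module docstring); the full 3^3 truth table is pinned in tests. A variant
ABSENT everywhere is an error, not a category. SVZ_TUMOR_SHARED spans
SVZ+either/both tumors; a subtype column records which tumors share it.

Patient labels follow the rule cascade (trunk link, then inter-tumor
evidence, then confident extinction of a primary-private variant, else
UNKNOWN). Design choices made where the procedure was genuinely open:

- Trunk evidence is any SVZ-tumor-shared variant present in all three
  tissues, not the TERT promoter specifically; `strict_tert=True` restricts
  to a trunk gene for sensitivity analysis.
- PRIMARY_ASSOCIATED takes precedence over SVZ_ASSOCIATED when both kinds of
  evidence coexist, because an inter-tumor-shared mutation is a direct
  genetic link between the tumors, which the SVZ-associated pattern excludes
  by definition.
- SVZ_ASSOCIATED requires at least one primary-private variant confidently
  ABSENT (not INDETERMINATE) in the recurrence; recurrent-private variants
  strengthen the verdict but are not required. No VAF cutoff is imposed on
  the extinct variant ("high allele frequency" is not operationalized as a
  threshold; presence calling already requires solid support).
- Patients without a recurrent sample are "not classifiable" rather than
  UNKNOWN: UNKNOWN is reserved for an evidentiary verdict after recurrence.

Cohort percentages are rounded half-up to one decimal (7/13 -> 53.8%,
11/17 -> 64.7%).

## Lineage trees

Variants are partitioned by exact three-state presence profile, then merged
by single linkage on the maximum per-sample VAF distance with tolerance tol
(default 0.05 VAF, roughly three binomial standard deviations at 1000x for
mid-range VAFs). Clusters are sorted by descending total VAF and attached
greedily: a parent must be PRESENT wherever the child is and dominate its
VAF within tol in every sample; among valid parents the one with the
smallest summed VAF excess wins (nearest ancestor), ties broken
lexicographically by cluster key; the germline root (VAF 0.5 everywhere, the
heterozygous ceiling) is always admissible. The descending-VAF order makes
cycles impossible. After construction the pigeonhole sum rule (parent VAF +
tol >= sum of children VAFs, per sample) is re-checked; violations and
orphans are recorded on the tree's `violations` list and surfaced, never
repaired by dropping variants. This is a deliberate simplification of
published lineage-tree search tools — sufficient to order trunk, primary and
recurrent clones, which is all the classification uses; error-aware
probabilistic search and CNV-adjusted CCF trees are out of scope.

Tree agreement is scored as the fraction of unordered mutation pairs whose
relation (same cluster / ancestor / descendant / unrelated) matches between
the inferred tree and the generating clone tree.

## Simulator

The generator emulates: a rooted clone tree whose trunk carries the shared
drivers; per-sample mutant-lineage purity and clone-fraction mixtures; the
diploid-heterozygous conversion VAF = 0.5 * purity * CCF, where a mutation's
CCF is the summed fraction of its carrying clone's subtree; Poisson-dispersed
total depth (fixed-depth switch for exact tests); and binomial alt counts at
p = vaf*(1-e) + (1-vaf)*e/3 (miscalls distribute uniformly over the three
alternative bases). Noiseless mode returns rounded expectations at exactly
the nominal depth, giving bit-identical tables regardless of seed. Truth
categories and the truth label are derived from clone membership through the
same category/classification definitions applied to exact presence, so
noiseless runs are an oracle for the whole pipeline.

Defaults, chosen once as realistic study conditions and not tuned:

- SVZ mutant-cell fraction U(0.02, 0.10) — "low-frequency" driver clones in
  tumor-free tissue, with no published numeric value to copy;
- tumor purity U(0.6, 0.9); residual trunk fraction in tumors U(0.05, 0.25)
  (plus an inter-tumor clone fraction U(0.1, 0.3) in primary-associated
  scenarios);
- 3-6 mutations per clone; miscall rate 1e-3; depth 1063 (panel median).

What the simulator does **not** model: copy-number alterations (the CCF->VAF
factor is fixed at 0.5, so CNV-shifted VAFs in real data will loosen VAF
clustering even though presence-based categories are unaffected), sequencing
batch effects, position-specific error, tumor-in-normal contamination of the
blood control, and spatial sampling bias within tumors. Passing simulation
benchmarks therefore demonstrates correctness of the decision logic under
the stated noise model, not robustness to every artifact of real panels.

The packaged 10-patient cohort fixture is a transcription of qualitative
per-patient sharing relations into synthetic count tables (present ≈ 250/1000
alt reads; trunk in SVZ ≈ 25-30/1000; absent 0/1000; indeterminate 0-1 alt at
depth 25-30); the two "unknown" patients are encoded as
indeterminate-blocked, one consistent reading of an undescribed evidentiary
failure.

## Problem sizes and numerics

Benchmarks run 200 patients per scenario (balanced SVZ-/primary-associated
truth) at depth 1063 plus a noiseless oracle scenario; power calibration uses
1e5 Monte-Carlo draws per (depth, VAF) grid point; lineage recovery uses 50
noiseless random scenarios. Binomial tails come from scipy.stats.binom;
k*(n) and power are memoized per parameter set. All randomness flows through
numpy Generator objects seeded from explicit spec seeds — no global RNG
state. Percentage rounding uses decimal half-up to avoid binary-float
round-to-even surprises.

## Known limitations

- Presence thresholds are declared defaults, not fitted to data; real panels
  may need site-specific error rates.
- The classifier is rule-based by design; it does not deconvolve subclone
  fractions (no PyClone-style clustering) and cannot distinguish an
  undetected early progenitor inside the primary tumor from an SVZ origin —
  that ambiguity is inherent to the sampling design, not the code.
- Lineage reconstruction assumes the copy-neutral heterozygous VAF model;
  amplified loci (e.g. EGFR) can violate containment and will surface as
  reported violations rather than corrected trees.
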