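# Methods

## Problem and coordinate model

The package predicts the regulatory role (activator vs repressor) of CRP
from a single binding site. A site is a closed integer interval
`[left, right]` on a continuous axis with the transcription start site
(TSS) at 0 and one nucleotide per integer; downstream of the TSS is
positive. Minus-strand sites are reflected onto this axis at parse time
(`rel_left = tss − right_abs`, `rel_right = tss − left_abs`), which makes
reflection an involution and keeps "downstream" meaning the same thing for
every site. Curated cores are 22 bp, so `right − left + 1 = 22` and the
site center `(left + right)/2` — the rules' *Region* variable — is always
a half-integer. This is why the canonical thresholds (−49.5, −28.5, 70.5,
…) are half-integers: they are exactly attainable centers of even-length
sites. *Region* semantics default to the center but can be switched to
the leftmost or rightmost position; the activation band of rule A1
(Region ≤ −49.5) sits upstream of the classical Class II anchor (−41.5)
under center semantics, and leftmost semantics moves the covered interval
far enough downstream to include it, so the switch is provided rather
than hard-coding one reading.

## Curation

Four filters in fixed order: TF name, evidence tier (strong = mutation
experiment support), TSS-redundancy removal, and core length = 22.
Redundancy removal drops *exact* duplicates — same TSS and identical
leftmost/rightmost positions — keeping the first occurrence; per-TSS
uniqueness would also discard genuinely distinct tandem sites, which is
not what "checking the leftmost and rightmost positions" implies. The
composition makes curation idempotent, which is asserted as a property.

## Descriptor (380 features)

| block | width | computed on |
|---|---|---|
| 4-mer counts, lexicographic | 256 | 42-bp extended sequence |
| 3-mer counts, lexicographic | 64 | 42-bp extended sequence |
| window overlaps L1–L17 | 17 | TSS-relative core interval |
| physicochemical | 3 | 42-bp extended sequence |
| global | 40 | 42-bp extended sequence |

The 42-bp extension adds k = 10 flanking bases per side (captured from
the reference promoter sequence, or recorded by the generator); a missing
flank is N-padded with a warning, and any k-mer window containing N
contributes nothing, so padding never fabricates composition signal.

Window overlaps are counts of integer positions inside both the site and
the window (`floor(min(hi)) − ceil(max(lo)) + 1`, clamped at 0), verified
against position-by-position enumeration. Four windows are fixed by the
published catalogue — L3 = [−35, −10] (core promoter spacer),
L6 = [−10, 2] (−10 box/TSS), L12 = [−60, 60], L15 = [−95, −35] — and the
other thirteen default to a tiling of [−120, 60] anchored on canonical
promoter landmarks (UP element, −35 box, downstream segments, whole
upstream/downstream spans, and ±11 bands around the Class I/II anchors
−61.5/−41.5). The defaults preserve the published indices of L3/L6/L12/L15
and the full catalogue is a constructor argument, so a user holding the
original window table can restore it exactly.

Physicochemical defaults are GC fraction, purine fraction, and the
Wallace-rule melting estimate Tm = 2(A+T) + 4(G+C): all pure functions of
base composition. Tm is kept in its conventional count form (units: °C
under the Wallace approximation) rather than per-base normalised, since
every descriptor here is computed on fixed-length 42-bp input.

The global block is 4 base fractions, 16 dinucleotide transition
frequencies (normalised over ACGT→ACGT steps), and for each base the
normalised 1-based positions of its first, 25%, 50%, 75% and last
occurrence (0 when absent) — 40 features.

Rule motif counts reuse the 4-mer block, i.e. they are counted on the
42-bp extension, forward strand; a `motif_scope="core"` switch restricts
all composition blocks to the 22-bp core for users who prefer the
narrower reading.

## Feature selection (IBCGA) and the SVM

The fitness of a feature mask is the pooled stratified k-fold
cross-validation accuracy of an RBF SVM on the masked columns (every
held-out prediction counted once; pooling avoids weighting small last
folds differently). k defaults to 24 so that a training set with 24
repressors places exactly one repressor per fold, maximising repressors
seen during training; when the smallest class is smaller than k, k is
reduced with a warning. (γ, C) are fixed for a run by a grid search on
the full feature set (defaults γ ∈ 2^{−9..1}, C ∈ 2^{−3..7}, odd powers;
ties resolved toward smaller C then smaller γ).

The IBCGA evolves a population of boolean masks with exactly r ones for
`generations_per_r` generations at each r, using elitism, binary
tournaments, uniform crossover followed by repair to exactly r ones, and
a swap mutation (one selected ↔ one unselected index). Size r+1 inherits
the whole population with one random unselected feature added per
individual. The best solution over the sweep, ties toward smaller r, is
S_m. An "intelligent" orthogonal-array crossover slot exists in the
config but the default is uniform-with-repair: the OA variant's design
parameters are not published, and the strategy interface isolates the
choice. Fitness values are memoized per mask within a run, which matters
because converged GA populations re-evaluate the same masks constantly.
No class reweighting is applied; stratification is the only imbalance
handling.

Determinism: one `numpy` generator seeded from the config drives every
stochastic step, so a fixed seed yields a bit-identical sweep.

## Rule model

A rule is a conjunction of predicates; each predicate confines one named
scalar (Region, or a 4-mer count) to a union of intervals with explicit
endpoint openness. The canonical four rules are shipped as data with the
printed thresholds. The paired region conditions of A1 and R1 are encoded
as unions (the two branches cover disjoint bands and are reported with
separate cover counts), since their literal conjunction would be empty.
Classification is first-match in the order [A1, A2, R1, R2]; all matching
rules are reported alongside, and an uncovered site yields `uncovered` by
default (configurable to majority-class fallback or delegation to the
SVM). Per-rule coverage follows the raw-antecedent accounting: coverage =
consequent-class matches / class total, accuracy = consequent-class
matches / all matches. Note these two views differ by design: under
first-match, a repression rule never sees a site already claimed by an
activation rule, but its raw antecedent may still match such sites.

The C4.5-style learner uses gain-ratio splits on continuous features with
candidate thresholds at midpoints between adjacent distinct values,
minimum leaf size 2, and pessimistic-error pruning at confidence 0.25
using the binomial upper confidence limit (Beta-quantile inversion; the
E = 0 case uses the closed form n(1 − CF^{1/n})). It is deterministic
given input order; split ties break by feature order then smaller
threshold. `extract_rules` converts each root-to-leaf path into a rule,
collapsing repeated bounds on one feature into a single half-open
interval `(lo, hi]`. The manual biological inference that condensed raw
tree paths into the four published rules is deliberately not automated:
the learner returns raw paths; the canonical set is shipped as the
published product.

## Evaluation

Repressor is the positive class. ACC, SEN, SPE and MCC derive from the
integer confusion counts; MCC is defined as 0 when its denominator is 0
(the all-one-class prediction case). Reported values are rounded to two
decimals; full precision is retained internally. ROC uses a threshold
sweep over unique scores with trapezoid area, which equals the
Mann–Whitney probability (ties counted half), asserted against an O(n²)
pairwise oracle at 1e−12.

## Synthetic data

The generator emulates the structure the method assumes, not real
promoters. Each site draws a ground-truth rule from a mixture whose
default weights are proportional to the canonical rules' cover counts on
the 169-site curated collection (88 : 31 : 14 : 7, remainder uncovered
≈ 17%); the default size is 169 sites with a 36/169 repressor target.
Placement samples the site's leftmost position so the center falls in the
assigned rule's *exclusive* region — the part of its band not claimed by
an earlier rule — and plants or suppresses motifs so that first-match
classification reproduces the assignment exactly (AACG inserted to defeat
A2 for R1 sites at Region ≤ −28.5; three TTTT occurrences defeat A1 in
the uncovered tail at Region < −80; required-absent motifs removed by
resampling, capped at 500 attempts with a diagnostic error). Five percent
of sites are placed exactly on rule thresholds (−49.5, 49.5, −28.5, and
the nearest representable half-integer centers −10.5/2.5 inside R1's open
bands) to stress endpoint handling. Cores carry the consensus G/G/C/C at
positions 5/7/16/18 with all other positions uniform; flanks are uniform
random and recorded so extension is exact. Labels are the assigned rule's
consequent; uncovered-tail labels are drawn to hit the overall repressor
target; label noise flips activator↔repressor with the configured
probability and the flip is recorded.

What passing the closed loop shows — and does not show: accuracy 1.0 at
zero noise verifies the ruleset, generator, descriptor and coordinate
conventions agree with each other exactly; it says nothing about how well
the four rules describe real CRP sites, whose labels are not generated by
the rules. Likewise, the SVM's near-perfect holdout accuracy on generated
data reflects that labels are a deterministic function of extracted
features there; published performance on curated data (test ACC/MCC
0.93/0.79) is instead checked by reconstructing the printed confusion
matrices from class sizes and sensitivity/specificity.

## Problem sizes and numerical choices

The recovery experiments run at desk scale chosen to keep the full suite
fast while leaving clear statistical margins: the planted-feature table
is 120 samples × 50 features with two informative columns (labels: sign
of their sum, kept ≥ 0.4 from the boundary so each planted column alone
carries ~0.85 single-feature accuracy — a gradient the GA can climb — and
the pair is perfectly separable); the GA uses population 30, 20
generations per r, r = 1…5, 5-fold fitness CV. Closed-loop and SVM
experiments use 300 sites. The C4.5 recovery uses 250 points on a
0.5-step Region grid, so "within one midpoint step" means within 0.5 of
−49.5.

## Known limitations

- The 13 non-published location windows, the physicochemical triple and
  the global block layout are documented defaults, not the original
  supplementary catalogue; all are overridable.
- The generator produces no genomic background, no correlated promoter
  structure, and no sites violating the consensus; screening specificity
  against real negatives is untested by construction.
- The exact published 12-feature model is not reproducible without the
  original database snapshot; the selection machinery is validated by
  planted-feature recovery instead.
- Uniform crossover stands in for the orthogonal-array "intelligent"
  variant (parameters unpublished); the hook exists for a faithful
  re-implementation.
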