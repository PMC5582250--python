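# Methods

## The discovery model

Conserved plant miRNAs are found by homology: a mature query matches an
EST window within a small substitution budget, and the locus is accepted
only if the surrounding sequence behaves like a pre-miRNA — it folds into
a stem-loop with the mature on one arm, pairs the star strand closely, and
is both thermodynamically stable and compositionally plausible. The
package separates that into orthogonal stages (scan, collapse, coding
filter, excise/fold, screen, targets, trees) with one `RunConfig` carrying
every threshold.

Key assumptions: homology at the mature level is ungapped (a 4-substitution
budget over ~21 nt is the operative definition of a conserved mature, so
gapped matches are not hits); EST orientation is arbitrary, so both strands
are searched and windows are folded in hit orientation; a single MFE
structure per window is kept (no suboptimal ensemble).

## Homology scan and redundancy

The scan computes the exact Hamming distance of every query against every
window on both strands (`N` never matches). This is strictly more
sensitive than a seeded heuristic search for this match class and has no
seeding artifacts; the brute-force double loop over windows serves as the
test oracle. Hits whose flanking regions (hit ± 200 nt) align at ≥ 95 %
identity with ≥ 90 % mutual length overlap are clustered (union-find);
one hit represents each cluster — from the longest EST, smallest accession
on ties, and within one EST the fewest-mismatch hit, so a cluster that
contains both arms of one hairpin is represented by the exact mature match
rather than the star-side echo.

## Coding filter

A database-free surrogate for protein-homology screening: an EST is
protein coding when its longest ORF across all six frames reaches
`min_orf_aa` (default 80). ORFs may start at AUG **or** at a sequence
edge and end at a stop **or** at an edge, because ESTs are fragments and a
truncated CDS must not be misread as non-coding. A consequence worth
knowing: a short sequence with a stop-free reverse frame has an edge-open
ORF spanning the whole fragment. The measured false-positive rate on
300-nt random background at 40 % GC is ≤ 5 % (Monte-Carlo in the test
suite); callers with a real protein-homology run can substitute a
precomputed exclusion list.

## Folding energy model

`mirhunt.folding` implements a Zuker-style minimum-free-energy dynamic
program over non-crossing canonical pairs (Watson-Crick + G:U) with an
embedded nearest-neighbor parameter set for the 37 °C / 1 M NaCl regime:

- stacking free energies for the 21 unique nearest-neighbor contexts
  (Watson-Crick values follow the published unified set; wobble contexts
  are weaker), symmetrized under reverse complementation;
- hairpin-loop initiation tabulated for sizes 3–9, bulge 1–6 and interior
  2–6, extended by Jacobson–Stockmayer 1.75·RT·ln(n/n₀) extrapolation;
  interior/bulge loops are capped at `max_loop_size` (30 nt);
- an affine multibranch penalty a + b·branches + c·unpaired with
  a = 3.4, b = 0.4, c = 0 kcal·mol⁻¹;
- no dangling ends, terminal mismatches or coaxial stacking — second-order
  for hairpin screening, and every downstream threshold is calibrated
  against this model through `RunConfig`, not against any external
  implementation.

Energies are integers in tenths of a kcal·mol⁻¹, so the DP is exact and
ties are well defined: minimal energy, then fewest pairs, then a fixed
decomposition order in the traceback (hairpin, then interior closings by
increasing indices, then multibranch). The open chain scores 0, hence
MFE ≤ 0 always. Correctness is established by two independent reference
routines shipped with the module: `exhaustive_mfe` (enumeration of every
valid pair set, scored by loop decomposition) must agree exactly with the
DP for short sequences, and `max_pairing` (a Nussinov-style pair
maximizer) checks the combinatorial layer separately.

`extract_hairpin` derives screening features purely from the pair list:
the arm is 5p/3p by the direction of the mature's partners (a window whose
partners straddle the terminal loop is `loop`, an unpaired window outside
any stem is `outside`); duplex mismatches are mature positions unpaired
against the star; the mature's largest internal break is its longest
unpaired run.

## Candidate excision and screening

Windows from a ladder of lengths (60–300 nt, clipped to the 50–350
precursor bounds) are placed with the mature 10 nt from either window end,
folded, and the structurally valid window with the most negative MFEI is
kept (ties go to the shorter window). Validity means: mature on one arm,
no unpaired run > 3 nt inside the mature, and ≤ 6 duplex mismatches. The
thermodynamic screen then applies MFE ≤ −15 kcal·mol⁻¹, MFEI ≤ −0.7,
GC 20–70 % and the length bounds; "≤" comparisons carry a 10⁻⁹ slack so
boundary values (−15.0, −0.70, GC exactly 20 or 70) pass deterministically.
The MFE/MFEI thresholds are keep-if-at-or-below: the intent of the screen
is to retain stable folds, and the package resolves the occasionally
ambiguous phrasing of threshold directions in that favor, prominently and
consistently. A 5′-U start and MFEI ≤ −0.85 (high confidence) are
reported, never filtered on. Tandem repeats (units 1–6 nt, ≥ 3 copies,
span ≥ 12 nt, maximal exact runs; the reported unit is as it appears at
the run start) annotate transposon-like content.

## Target scoring

The expectation scheme is pinned to the defaults of the standard plant
target-prediction tool family: WC 0, G:U 0.5, mismatch 1, gap 2, all
doubled at miRNA positions 2–13, cutoff 3.0, ≤ 1 gap; sites are found by
exhaustive sliding of the reverse-complemented miRNA with both single-gap
registers, deduplicating overlaps to the best score. Translation
inhibition is called when any non-WC column falls at positions 10–11
(the slicing site), cleavage otherwise. Target-accessibility (UPE)
scoring is deliberately omitted — it needs ensemble folding and does not
change the complementarity ranking tested here.

## Phylogenetics

Family distances are 1 − identity from global Needleman–Wunsch alignments
(match +1, mismatch −1, gap −2; identity = matches / alignment columns).
A progressive multiple alignment is unnecessary for distance-based NJ, so
none is built. Neighbor joining is the standard Saitou–Nei agglomeration
with the Q criterion; ties break toward the smallest index pair, negative
branch-length estimates are clamped to zero (logged), and the result is
an unrooted tree serialized with a trifurcating root. On additive
matrices the reconstruction is exact to machine precision, which the
tests verify against independently generated random trees.

## Synthetic data: what it emulates, what it does not

`synthetic` builds EST collections with known ground truth. Planted
precursors are mutated matures (0–4 substitutions) folded back on a
near-reverse-complement star carrying 0–3 planted non-pairing positions
(kept away from the duplex ends and the 2-nt 3′ overhang), embedded on
either strand with random flanks at the background GC. Loop and overhang
residues are drawn from {A, C} — mutually non-pairing bases — so the
planted duplex is the unambiguous optimum of the fold; with fully random
loops a few percent of plants fold off-register and the truth table would
mislabel them. Coding decoys carry a ≥ 100-codon ORF, repeat decoys a
≥ 24-nt tandem run, and background ESTs are i.i.d. residues at 40 % GC
(the genome-wide average of the crucifer this method class targets),
200–800 nt.

The default benchmark (30 plants, 100 background, 10 coding and 5 repeat
decoys) rejection-samples each plant until its EST, excised and screened
in isolation, passes every criterion: the benchmark's premise is that the
planted precursors *are* compliant, so recall measures the pipeline's
recovery machinery rather than the thermodynamic lottery of a particular
random draw. Typical results are recall 0.97–1.0 (residual losses are
coding-filter false positives on random flanks, consistent with the
measured ≤ 5 % rate) and precision 1.0 — random background at 40 % GC
essentially never survives both the homology and MFEI filters.

What the generator does **not** emulate: real codon usage, sequencing
error, expression-biased EST sampling, genomic repeat families beyond
exact tandem runs, and paralog structure within miRNA families. Passing
benchmarks therefore demonstrate the machinery is correct and calibrated
on its stated model, not that sensitivity on a real dbEST collection
would match.

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale inputs chosen
to exercise every code path: 200 enumeration-checked folds (≤ 12 nt),
20 × 50 scan-oracle instances, 20 additive NJ trials, and the 145-EST
benchmark; a full benchmark run takes seconds on one core (the folding
and alignment kernels are numba-compiled). Every random draw flows from
an explicit seed through `numpy.random.default_rng`; pipeline reruns with
the same seed and config produce byte-identical artifacts, which is
asserted in the test suite.
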