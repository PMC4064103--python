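# Methods

## Model and procedure

`hierfold` predicts RNA secondary structures under the hierarchical
folding hypothesis: a pseudoknot-free structure G forms first; further
pairs G′ are then added — possibly crossing G — to lower the free energy.
All engines minimise the same additive loop-based free energy over the
density-2 class, and all report energies produced by the standalone
evaluator (every `FoldResult` is re-scored on return; a mismatch is a
hard error, which in practice makes the evaluator the single source of
truth for the objective).

### Secondary structures and the density-2 class

A structure is a set of pairs i.j (1-based, i < j) with at most one
partner per base; pairs must be canonical (A-U, C-G, G-U).  Pairs i.j and
k.l *cross* iff i < k < j < l.  Crossing-involved pairs group into
*bands* (maximal pseudoknotted stems occupying two sequence intervals),
and bands connected by crossing form a *pseudoloop*.

The class handled by the folding engines is defined operationally, and
the same definition is shared by the class checker, the energy evaluator,
the exhaustive oracles and the dynamic programs:

1. the crossing graph is bipartite — the pair set splits into two
   pseudoknot-free layers; and
2. within each pseudoloop, no base is enclosed by the spans of more than
   two of its bands.

Exhaustive enumeration of band arrangements (2–6 bands) shows this class
is exactly the *linear chains of interleaved bands* — H-type pseudoknots
(2 bands), kissing hairpins (3), longer chains — plus arbitrary *nested*
pseudoknotted substructures, which form their own pseudoloops and
therefore do not count against the enclosing pseudoloop's cover.  Reading
condition 2 with band *intervals* instead of spans would make it vacuous
(distinct bands' left intervals are provably disjoint, as are right
intervals) and would admit nested-interleaved arrangements that the
class description ("no base enclosed by more than two overlapping
pseudoknotted stems") excludes.  Structures at the margin of the class
may be classified differently than by other density-2 implementations;
internal consistency is what the package guarantees.

Band grouping is deterministic: within a layer, two directly nested
crossing-involved pairs belong to the same band unless some pair has
exactly one endpoint in one of the gaps between them (such a pair forces
a band boundary).  A consequence matching the relaxed-stem convention:
stems separated by small empty internal loops (including bulges of 1)
remain a single band, scored with the band-spanning loop terms.

### Energy model

All energies are integers in hundredths of kcal/mol.  Products with the
band factors round half away from zero, so 0.89·e_S and 0.74·e_int are
exact, reproducible integers and energy ties are exact.

Ordinary loops: hairpin initiation by loop size (minimum 3 unpaired
bases; smaller hairpins are infeasible and score +∞), stacking energies
keyed by the two closing pairs, bulge and internal-loop initiation by
size with a linear asymmetry penalty (0.50/unit, capped at 3.00) and
logarithmic extrapolation beyond the tabulated sizes, and the multiloop
linear form a + b·pairs + c·unpaired (the closing pair counts toward
`pairs`).

Pseudoloops: P_x + P_b·bands + P_up·unpaired + P_ps·closed-subregions,
with P_x ∈ {P_s exterior, P_sm inside a multiloop, P_sp inside another
pseudoloop}.  Inside a band, consecutive chain pairs connect by
band-spanning stacks (0.89·e_S), band-spanning internal loops
(0.74·e_int), or band-spanning multiloops (a′ + b′·pairs + c′·unpaired)
when a gap holds closed subregions.  Conventions chosen where the
taxonomy is silent, applied consistently by evaluator and engines:

* a loop containing a pseudoloop child is a multiloop (even with no other
  branch); the pseudoloop child contributes P_sm but no `b` term, since
  it is not a base pair;
* a pseudoloop directly inside a pseudoloop interior charges P_sp and is
  not additionally counted as a P_ps closed subregion;
* a pseudoloop's interior is its span minus its bands' intervals;
  interior closed subregions are the maximal ordinary closed regions
  directly inside it (P_ps each).

The shipped default parameter set (`params/default.par`) is a compact,
self-consistent test set: a 6×6 stack table obeying the physical
180°-rotation symmetry, size-indexed hairpin/bulge/internal tables, and
the pseudoknot constants listed in the README.  It deliberately omits
tetraloop bonuses, bulge-of-1 stacking and helix-end penalties; the
loader accepts richer tables in the same format.  All folding properties
asserted by the tests are table-agnostic except the pseudoknot constants
and the two band factors.

### Folding engines

One dynamic program serves four entry points (plain MFE, constrained
MFE, HFold, HFold-PKonly), differing only in which pairs may form:

* ordinary layer — Zuker-style matrices V (closed region), WM (multiloop
  partial) and W (external), with forced input pairs excluded from ever
  being unpaired or re-paired; internal loops are capped at 30 unpaired
  bases per side (a standard search bound, not a model statement);
* pseudoloop layer — a chain DP: a pseudoloop is built left to right as
  a chain of bands strictly alternating between the fixed layer (runs of
  input-structure pairs) and the added layer (helices over free bases),
  with interior segments scored by a WI matrix (P_up per unpaired base,
  P_ps + energy per closed subregion, P_sp + energy per nested
  pseudoloop).  Because every crossing in a two-layer structure joins a
  fixed-layer pair with an added-layer pair, strict alternation is
  complete for the class, and with an empty input structure no
  pseudoloop can form — HFold(∅) is plain MFE folding by construction.
  Chain states are keyed by their start and the embedded previous
  interval, not by the caller's region, which keeps the state space
  tractable on pairing-dense sequences.

Tracebacks re-read the recorded argmin of each cell; candidates are
scanned in a fixed order and only strict improvements replace the
incumbent, so outputs are deterministic.  Ties between the four
orchestrator methods go to the lowest method index.

The *normative semantics* of HFold and HFold-PKonly is the exhaustive
oracle: enumerate every pseudoknot-free added layer over the bases
unpaired in G (crossing-only for PKonly), keep unions passing the shared
density-2 checker, and score with the evaluator.  The acceptance suite
asserts engine = oracle on 200 random instances per engine (n ≤ 16–18,
structured base composition); at those sizes the oracle reaches H-type
pseudoloops, multi-band chains and revised-input scenarios.

"External unpaired bases" (method 4) are bases unpaired in G and not
enclosed by any pair of G; removed bases are never re-introduced as
paired after the constrained fold is lifted back to original
coordinates.  Method 4 with an empty input returns the empty structure
rather than failing, so batch runs never abort.

### Seeding

Hotspot stems approximate a heuristic first phase: every canonical pair
is given its best inward extension chain under the relaxed-stem
connectivity (stacks, bulges of 1, 1×1/1×2/2×1 loops), scored by plain
stack/internal terms; chain heads that are not absorbed by a better
enclosing chain and have ≥ 3 pairs and negative energy become stems,
ranked by energy then 5′ index.  A chain may only terminate on a pair
that can close a legal hairpin.  This is a deterministic approximation —
the reference heuristic's exact stem scoring is not reproduced.  The
suboptimal-structure list is an explicit surrogate: the MFE structure
plus one constrained refolding per hotspot stem, deduplicated and sorted
by energy.  It is not equivalent to a true suboptimal enumeration
algorithm; it merely supplies diverse low-energy pseudoknot-free seeds.

### Evaluation protocol

Accuracy is per-pair: sensitivity = correct/|reference|,
PPV = correct/|prediction|, F = harmonic mean, all defined as 0 on zero
denominators.  G_big is a maximum-cardinality pseudoknot-free subset of
the reference computed by an interval DP (ties resolved to the
lexicographically smallest pair list); G_small is the remainder.

Bootstrap 95% percentile CIs resample the F-measure vector with
replacement at its own length (10⁴ resamples by default) and report the
2.5th/97.5th percentiles of the resampled means, using linear
interpolation between order statistics.  The two-sided permutation test
counts label reassignments whose |Δmean| ≥ the observed |Δmean|; when the
number of distinct splits is ≤ 10⁶ all splits are enumerated (identity
split included) making small tests exact, otherwise 10⁴ random splits
are drawn.  Both are bit-reproducible given a seed.

The robustness driver samples each pair of G_big independently with
probability α (default grid 0.01, 0.05…0.95, 0.99; 100 replicates),
runs the chosen predictor on every subsample, scores F against the full
reference, and emits a tidy per-replicate table plus per-α summaries
(mean F and the bootstrap CI of per-replicate mean F).  A predictor
failure on one input is recorded as F = 0 with a warning and the run
continues.  Aggregation across molecules is reported both pooled and
per-molecule, since either view can be of interest.

## Synthetic data

`generate_fixtures` plants known structures in random sequences:
hairpins, H-type pseudoknots (two crossing helices) and kissing-hairpin
chains (two hairpins joined loop-to-loop by a third helix).  Helix base
pairs are drawn GC-biased; spacers are A-biased so the planted signal
dominates.  Every reference is canonical, density-2 and round-trips
through dot-bracket notation.  What the fixtures do *not* emulate:
natural sequence composition and covariation, non-canonical pairs,
modified nucleotides, and competing near-optimal structures of real
molecules — so passing tests demonstrate algorithmic correctness under
the model, not predictive accuracy on biological data, which depends on
the richness of the parameter tables supplied.

## Problem sizes and numerical choices

The test suite exercises oracle equivalence at n ≤ 16–18 (the scale at
which exhaustive enumeration is exact and fast), structural contracts
and the robustness trend on planted fixtures of 25–40 nt (120
predictor runs across 20 sampling seeds for the trend), and scaling on a
200-nt fixture.  These sizes were chosen so the full suite illustrates
every code path in minutes on one core; the engines themselves handle
hundreds of nucleotides (sparse, designed 200-nt inputs fold in about a
second; pairing-dense random 200-mers take tens of seconds because the
pseudoloop search space grows with the number of canonical helices).

Determinism: fixed-point energies; half-away-from-zero rounding for the
band factors; fixed candidate scan orders with strict-improvement
updates; brute-force tie-breaks by fewest pairs then lexicographic pair
order; bracket families assigned first-fit greedily over `( [ { <`.

## Known limitations

* No dangling ends, coaxial stacking, tetraloop bonuses or helix-end
  penalties; no base triples, G-quadruplexes or modified nucleotides.
* Lonely pairs are permitted by the folders; the shipped tables make
  them energetically unattractive rather than forbidden.
* The engine searches band chains whose interiors connect by stacks and
  internal loops; band-spanning multiloops and pseudoloops nested inside
  band gaps are scored by the evaluator but not proposed by the search.
  In the operational class these shapes require substantially longer
  sequences than the oracle-verified regime.
* No partition function or base-pair probabilities.
* Hotspot and suboptimal seeding are documented approximations, not
  reimplementations of the reference heuristics.
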