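# Methods

## Problem

Classic inverse RNA folding asks for a sequence whose minimum-free-energy
(MFE) secondary structure equals a given target. `rnaforge` solves the
*extended* problem: the structural constraint is deliberately relaxed from
the exact structure to its coarse-grained **shape**, and two physical
attributes are added as design goals — thermodynamic stability (the MFE
ΔG, kcal/mol) and mutational robustness (**neutrality**, a number in
[0, 1]). The motivating use case is designing sequences for which a
functional stem-loop must be strictly preserved while a distant motif may
gain or lose a nucleotide, as long as the global architecture and the
physical attributes match those of a natural RNA (miRNA precursors, for
example, are measurably more stable and more robust than random sequences
with the same structure).

## Shape abstraction

A structure is abstracted to an ordered, labelled, weighted tree over
motif types: stacks (S, weight = stacked pairs), hairpin loops (H), bulges
(B, unpaired bases on exactly one strand), interior loops (I, both
strands), multiloops (M, ≥ 3 emanating helices; weight may be 0), external
runs (E), under a virtual root R. Construction rules: any unpaired base or
branching terminates a stack (no lonely-pair smoothing); children are
ordered 5'→3'; each external run is its own E node. Weights partition the
sequence exactly: 2·ΣS + ΣH,B,I,M,E = L, which the suite asserts on random
structures. The canonical linear form, e.g. `((((H3)S2)B1)S2)R`, parses
back losslessly. ViennaRNA's `b2shapiro` differs only in wrapping the
string in one extra parenthesis pair and pooling all external bases into a
single trailing E; the test suite cross-checks our strings against Vienna
on structures where the dialects coincide.

Whether the shape term uses weighted or unweighted trees is configurable
(`DesignGoals.weighted_shape`); the default is weighted, the stricter
reading.

## Distances

* **Base-pair distance**: cardinality of the symmetric difference of the
  pair sets; a metric on equal-length structures.
* **Shape distance**: ordered tree edit distance (Zhang–Shasha keyroot DP)
  between shape trees under a declared cost model: indel(n) = weight(n);
  relabel = |Δweight| for same-type nodes, weight sum otherwise;
  relabel(R, R) = 0. For unweighted trees this degenerates to unit costs.
  The exact cost table of ViennaRNA's `RNAdistance` is not documented and
  measurably differs (a hairpin weight change of 1 costs 2 there); the
  model here is therefore declared, test-anchored against an independent
  brute-force forest-distance recursion, and override-able via
  `EditCosts`.

## Folding backends

All thermodynamics flow through a pluggable backend:

* **vienna** — RNAfold via the ViennaRNA Python bindings, default
  parameters; the production engine.
* **toy** — a Nussinov-style DP in which each stack of adjacent pairs
  contributes −(bond₁+bond₂)/2 pseudo-kcal/mol (bond GC = 3, AU = 2,
  GU = 1), loops are free, hairpins hold ≥ 3 unpaired bases and every
  helix ≥ 2 pairs (no lonely pairs). The DP (numba-compiled; recurrences
  in `_toyfold.py`) is exact for this model: the suite verifies it against
  exhaustive enumeration of all valid structures for lengths ≤ 14. Ties
  among co-optimal structures are broken deterministically by the
  traceback's fixed branch order.

The toy model is hermetic and ~100× faster than a Turner-model fold, which
is what makes exhaustive neutrality evaluation and 50-run panels cheap. It
reproduces the qualitative landscape features the designer exercises
(competing helices, register shifts, stability ordering of GC/AU/GU) but
none of the Turner loop penalties, dangles or temperature dependence —
panel results certify the *algorithm*, not transferability of any specific
sequence to the laboratory; for that, design with `--backend vienna`.

Folds are memoized per backend instance; neutrality evaluation makes the
cache load-bearing (thousands of near-duplicate folds per design step).

## Neutrality

η(s) = (1/3L) Σ_m [1 − d_bp(S₀, S_m)/L] over all 3L single-point mutants
m, where S₀ and S_m are MFE structures. Exhaustive enumeration (no
sampling) keeps the objective noise-free; normalising by L rather than by
pair count keeps η ∈ [0, 1] for every structure including the open chain.
This is the standard robustness definition in the extended-inverse-folding
lineage; the source literature does not restate its exact normalisation,
so the formula is declared here and a config hook allows substituting a
tree-distance-based variant.

## Objective and search

For candidate sequence s with MFE fold (S, ΔG):

F(s) = w_n·|η* − η(s)| + w_g·|ΔG* − ΔG| + w_s·d_tree(shape(S), shape*) +
w_b·d_bp(S, target)

Defaults w = (500, 2, 200, 1). Calibration logic: the shape term must
dominate — no achievable gain in the other terms may ever pay for breaking
the shape. The largest realistic neutrality pull is |Δη| ≈ 0.3 ⇒ 150
units, so one tree-edit unit is priced at 200. Within the shape-preserving
set, a 0.01 neutrality gap trades against a 2.5 kcal/mol stability gap,
and the base-pair term (the cheapest) merely breaks ties toward the
original target structure, preventing pure shape-matching drift. With
w_s = 50 (an earlier calibration) panel runs on short targets did trade
one tree-edit unit for an exact neutrality match, which is precisely the
behaviour the dominance rule exists to forbid.

Search proceeds in two phases per run:

1. **Init + adaptive walk** (the RNAinverse-style stage): a random
   sequence compatible with the target (paired positions uniform over the
   six canonical pair types, unpaired uniform over ACGU), then a greedy
   best-improvement walk over all 3L point mutants minimising base-pair
   distance, ties broken by position then residue order. A walk can
   strand in a local minimum, so up to 20 fresh random starts are tried
   until one reaches distance 0 (the best stranded walk is kept
   otherwise).
2. **Simulated annealing with look-ahead**: per step, `samples_per_step`
   (default L) candidates at Hamming distance uniform in {1..lookahead}
   (default 4; sampled, not exhaustive); geometric cooling T_k = T0·αᵏ
   with T0 from a warm-up (median |ΔF| of 50 random proposals, scaled for
   ≈ 50% initial acceptance) and α set so T_steps ≈ 10⁻³·T0; worsening
   moves accepted with probability exp(−ΔF/T). The best-so-far sequence is
   returned, so the reported objective is non-increasing in the step
   index. Default 300 steps.

Two engineering layers sit on top, both config-off-able and both absent
from the algorithm's published description (they are this package's own
choices): a **two-stage evaluation** computes the cheap structural terms
for every candidate and pays the 3L-fold neutrality price only for the
best screened candidate per step (`exact_objective=True` disables); a
**greedy polish** on the full objective (≤ 5 rounds) after annealing
removes small residuals the cooling schedule left behind. If a run's best
design still misses the target shape, the run restarts from scratch (≤ 2
restarts) — strict shape conformance is the tool's contract, and a
restart is cheaper than a longer schedule.

Setting T0 = 0 with exhaustive per-step enumeration and exact evaluation
makes the annealer accept exactly the adaptive walk's moves; this
reduction is asserted move-for-move in the suite.

`design()` runs n independent seeded pipelines (seeds derived from one
master seed; byte-identical reports on repetition) and returns results
sorted by rank score — the shape distance of the design, ties broken by
objective then seed. The rank score is shape-level by default; whether the
published ranking used full-structure or shape trees is ambiguous, so a
flag can switch.

The `-e`/"tie the ends" option is implemented as a proposal bias: the two
residues at the target's outermost helix terminal pair are kept canonical
by resampling one of them when needed; its published description is a
single line, so this declared semantics is ours.

## Synthetic targets and the sensitivity panel

`gen_structure(length, topology, rng)` emits valid structures (balanced,
hairpins ≥ 3, no lonely pairs) in three classes — hairpin, bulged
(bulge or interior loop), multiloop (three-way junction) — which between
them cover every shape node type. Motif sizes are random compositions of
the length budget, so helix lengths, loop sizes and external runs vary.

The sensitivity panel (the acceptance surface, and `scripts/acceptance.py`)
asks the question "when the user moves the dials, does the output follow?"
concretely: 10 generated targets of 30–60 nt (topologies cycled), each
admitted only after an adaptive walk from a random start actually reaches
the target (so the goals are achievable by construction), desired ΔG and η
set to the values realised by that reference sequence, 5 independent
design runs per target with the toy backend and default weights. Reported:
the worst-case percent deviation of achieved η and ΔG from their desired
values over all 50 runs, and the shape distance of every design. Measured
at master seed 1: worst deviation ≈ 2% (dG), ≈ 0.2% (η), all 50 shape
distances exactly 0, ≈ 8 minutes on one CPU. The 30–60 nt / 50-run scale
is the package's chosen desk-scale protocol; the published-scale protocol
(one ~100-nt natural target, 1000 Vienna-backend runs, hours) ships as
`scripts/reproduce_tables.py` and takes the external target structures as
input.

## Numerical and degenerate-input choices

* Toy energies are multiples of 0.5, exact in floating point; DP
  traceback equality tests are therefore safe.
* Open chain: ΔG = 0 by convention; shape is `(En)R`; neutrality of a
  sequence with no foldable mutants is exactly 1.
* Minimum hairpin size 3 is enforced at parse time so no accepted target
  is unattainable by construction; pseudoknots are rejected (single
  bracket alphabet).
* T in input sequences converts to U with a warning; 0-based coordinates
  internally, 1-based in all messages and reports.
* Co-optimal toy folds are resolved by a fixed traceback branch order
  (pairing preferred, smaller helix extension first); neutrality is
  consequently deterministic but its oracle comparison is restricted to
  tie-free sequences, where the value is implementation-independent.

## Known limitations

* The toy model omits loop-size penalties, so it over-favours long loops
  relative to the Turner model; achievable toy targets are not always
  achievable under Vienna and vice versa.
* Neutrality costs 3L folds per evaluation; exact-objective annealing on
  100-nt targets with the Vienna backend is minutes-per-run.
* The weighted-shape default means loop-size changes count toward the
  shape distance; users wanting the looser topology-only relaxation
  should set `weighted_shape=False`.
* Objective weight constants and the tree-edit cost table are declared
  calibrations, not published constants; both are configurable and all
  reported numbers carry the backend identifier for attribution.
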