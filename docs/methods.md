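# Methods

This note documents the model, the synthetic study conditions, and the
numerical and design choices behind `retroranker`, in the spirit of the
methods documentation of packages like statsmodels or msprime: enough detail
to judge what the computations do and what passing tests do and do not show.

## Inputs and the change annotation

The unit of input is one candidate of a retrosynthesis prediction: a product
molecule and one predicted reactant set, linked by an atom map
(`[CH3:1]`-style numbering, as produced by tools such as RXNMapper; this
package consumes maps, it never creates them). Hydrogens are implicit
throughout; all atom counts are heavy-atom counts.

The change annotation diffs the bonds of the two sides keyed by atom-map
pairs. A bond between two mapped atoms that exists only on the reactant side
is *broken*, only on the product side *formed*, and on both sides with
different order *order-changed*; the three sets are disjoint by construction
and each changed bond counts once. Reaction-center atoms are the map numbers
incident to any changed bond — including mapped leaving atoms, which is why
an esterification written with a mapped acid hydroxyl has two changed bonds
(one broken to the leaving oxygen, one formed). Reactant atoms that are
unmapped or whose map number is absent from the product are leaving-group
atoms. Unmapped *product* atoms are rejected as a mapping error: in the
retrosynthesis direction every product atom must come from somewhere.

Both sides are compared in their aromatized forms, so two kekulé drawings of
the same ring never register as order changes. The "reacted atoms in the
neighborhood" feature is a breadth-first count of center atoms within radius
r of each atom (the atom itself excluded); r defaults to 1 (immediate
neighbors) and is exposed in every API that computes annotations, since no
canonical value exists.

## Featurization

Atom vectors concatenate molecular features — element one-hot over 20 common
elements plus an "other" bucket, degree one-hot (0–5), formal charge,
aromatic flag, total-H one-hot (0–4), ring flag — with change features:
center flag, reacted-neighbor count as a clipped one-hot (0–4+), leaving
flag, and leaving-group size as a clipped one-hot (0–4+), where the size is
the heavy-atom count of the connected component of leaving atoms the atom
belongs to. Counts are clipped one-hots rather than raw integers so feature
scales stay bounded. Bond vectors carry order one-hot, ring flag,
conjugation flag, and a changed-bond flag. Leaving-group slots are
structurally zero on the product side, which keeps the two sides on one
schema so both encoders share an input format.

The schema is declared data (ordered name/width pairs); its hash is stored
in checkpoints and verified at scoring time, so a model can refuse features
it was not trained on.

## Model

Each side of the reaction is encoded by an independent attention-gated
message-passing network (the attention-gated family of molecular GNNs;
any node-order-invariant aggregator would do and the backbone sits behind an
interface). Per layer, each directed edge computes a message from its source
state and edge embedding, gated by a sigmoid of (source, destination, edge);
gated messages are sum-aggregated at the destination and combined with the
current state through a ReLU update with a residual connection. The readout
initializes a per-graph context as the mean node state and refines it for a
configurable number of steps with softmax attention over nodes. Sum and
softmax aggregations make the encoder exactly permutation-invariant up to
floating-point associativity (verified to 1e-5 in tests; float64 throughout).

The reaction representation is the concatenation of the reactant-graph and
product-graph embeddings (width 2×hidden); a two-linear-layer scorer with a
ReLU between maps it to the scalar re-ranking score. Defaults: hidden width
64, 3 message-passing layers, 2 readout steps, Glorot-uniform initialization.
These are pragmatic CPU-scale defaults, declared in `EncoderConfig`.

Because no deep-learning framework is part of the dependency set, the model
runs on a purpose-built reverse-mode autodiff core over NumPy
(`retroranker.autodiff`): dense matmuls, elementwise ops, row gathers, and
constant-sparse-matrix products for edge-to-node aggregation and node-tograph
pooling. Gradients are verified against central differences in the test
suite.

## Training objective

For each product with a recorded candidate, training pairs (recorded,
sampled non-recorded) are built; by default negatives are re-sampled each
epoch under a per-product pair budget (default 3), which uses more of the
candidate list than freezing one sample — both modes are config options. The
loss is the two-class label-smoothed cross-entropy on the score margin
z = s⁺ − s⁻ with target (1−ε, ε):

  L(z) = (1−ε)·softplus(−z) + ε·softplus(z).

At z = 0 the loss equals ln 2 for every ε. For ε = 0 it decreases strictly
everywhere; for ε > 0 its minimum sits at z = ln((1−ε)/ε) and the loss rises
beyond — label smoothing deliberately discourages unbounded margins. Tests
assert strict decrease on the decreasing region only, which is the correct
property of this parameterization. Default ε = 0.1.

Optimization is Adam (lr 3e-3, batch 256). Model selection is by validation
pairwise accuracy (fraction of validation pairs with s⁺ > s⁻), not by loss,
because pairwise accuracy is the quantity the ranking objective actually
targets; with no validation data the final epoch is kept. With a fixed seed
the entire run is reproducible to the last bit (single-threaded NumPy ops,
seeded samplers).

Candidates whose SMILES fail to parse are retained as "unscorable" sentinels
carrying −∞ score, so re-ranking is always a permutation of the original
list and top-k accuracy denominators are preserved; how real upstream beam
searches handle such candidates varies, and this policy is this package's
choice.

## Re-ranking strategies

`S1(p, k)`: among candidates at original rank > k, the ⌊p·(n−k)⌋ with the
lowest scores are moved to the end of the list, re-ordered by score
descending; everything else keeps its relative original order and positions
1..k are untouched. The ratio is taken over the tail rather than all n so
that p = 1 demotes exactly the whole movable set (a config switch restores
the all-n reading, which differs only for k > 0). Score ties at the quota
boundary keep the candidate with the better original rank out of the demoted
set; all orderings fall back to original rank ascending, making every
permutation deterministic.

`S2(p, k)`: ascending sort of (original rank + S1 rank), ties by original
rank. With p = 0 both strategies are the identity; S2(1.0, 0) is the
rank-sum ensemble of the original model and the ranker.

Both implementations are tested for exact agreement with independent
brute-force transcriptions of these definitions on thousands of random
instances with injected score ties, and exhaustively for all n ≤ 7 on the
invariants (permutation, head preservation, identity cases, demotion-set
monotonicity in p).

## Synthetic study conditions

The generator emulates the *output* of a frequency-biased single-step model,
not its internals. Products are built by splicing two random substituents
(alkyl chains, branched alkyls, benzyl/phenethyl; optionally an
ester-containing substituent with probability 0.15 to create second
disconnectable sites) around one of four template cores, with template mix
ester 0.45, amide 0.30, N-alkylation 0.15, C–C coupling 0.10 — a frequent-to-
rare spectrum. Atom maps are assigned at rewrite time, so every candidate is
mapped correctly by construction. Recorded reactants undo the spliced bond
and attach the template's leaving group (hydroxyl, bromide, or two bromides
for the coupling); each recorded candidate plants exactly 1 changed bond and
1–2 leaving atoms, and the generator records these planted values so that it
and the change detector act as mutual oracles in tests.

Decoy operators: wrong-site (disconnect a different template motif of the
same product — feature-wise indistinguishable from a correct disconnection,
the selectivity failure mode), spurious (recorded reactants plus one extra
unmapped substituent), no-op (the product offered as its own precursor, zero
changed bonds), over-large (the recorded disconnection with an 8–9 heavy-atom
leaving group). Default mix 0.25/0.30/0.15/0.30; duplicate candidate keys are
avoided while a retry budget lasts and the recorded key is never duplicated.

Original ranks: every candidate receives log-score β·ln f + σ·g, where f is
the frequency of the pattern the candidate mimics (recorded candidates use
their true template frequency; decoys mimic patterns drawn proportionally to
frequency), g is standard normal and σ = 1. β = 0 gives exactly uniform
recorded ranks (verified by a chi-square test); the default β = 1.5 produces
a broad recorded-rank distribution with baseline top-1 near 0.10–0.15 —
rare-template recorded candidates sink while frequent-template ones still
rank well, which is the bias pattern re-ranking can exploit. A design-time
analysis of the S2 rank-sum arithmetic under an idealized scorer showed that
this broad-bias regime is the one where the ensemble strategy is effective,
which is why the default is moderate rather than extreme: with recorded
candidates forced to the very bottom, S2's respect for the original ranking
caps what any scorer could recover.

What the generator does *not* emulate: realistic USPTO chemistry coverage,
stereochemistry, multi-product reactions, reagent-dependent selectivity, or
upstream models whose errors correlate with molecular size. Passing the
recovery experiment therefore shows that the pipeline learns and exploits
planted change-feature structure under frequency bias — not that it improves
any particular public benchmark.

## The desk-scale experiment

The canonical experiment (`retroranker.experiment`, also run by
`scripts/acceptance.py` and the headline acceptance test) uses 2,000
training and 500 test products, 10 candidates each, the separable decoy mix
(wrong-site excluded, since those decoys are feature-identical to recorded
disconnections by construction), β = 1.5, and a 32-wide 2-layer encoder
trained 10 epochs with pair budget 3 — sizes chosen so the full pipeline
runs in about two minutes on one CPU while leaving the accuracy estimates
stable to a few points. Typical results (seed 1): baseline top-1/top-3
10.8%/27.8% versus re-ranked 32.4%/64.0% under S2(1.0, 0), final-accuracy
position 10 → 8, validation pairwise accuracy 100%.

## Numerical choices and degenerate inputs

Float64 everywhere; softplus and sigmoid in numerically stable forms; the
per-segment max is subtracted before segment softmax (a constant shift,
gradient-neutral). Graphs with a single atom and no bonds are valid inputs
(aggregation contributes zeros). Empty candidate lists, empty datasets,
empty grids, rank gaps, duplicate recorded candidates, ε ≥ 0.5 and p ∉ [0,1]
are rejected with typed errors. Reagent fields in three-part reaction SMILES
are discarded — the model sees reactants and product only. The recorded
match uses canonical-SMILES string identity (maps stripped, fragments
sorted), which is sound for parseable SMILES and far cheaper than graph
isomorphism.

## Known limitations

* The change annotation trusts the atom map; a wrong map yields wrong (but
  well-defined) features, and no map-repair pass exists.
* One backbone (attention-gated message passing) is implemented; the encoder
  interface admits others, e.g. a graph transformer, but none ships.
* Scoring large prediction files is CPU-bound Python/NumPy; throughput is
  adequate for desk-scale studies, not for USPTO-full-scale inference.
* Stereochemistry is ignored end to end (canonicalization keeps whatever the
  toolkit preserves, features encode none of it).
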