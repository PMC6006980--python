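# Methods

## Scope and approach

`pksline` performs the in-silico half of characterizing a modular type-I
PKS gene cluster: motif-validated domain detection in the deduced PKS
proteins, functional subtyping of the catalytic domains, phylogenetic
placement of acyltransferases, partitioning of the domain string into
modules, and colinearity-based prediction of the product backbone with
stereochemistry, reconciled against an observed structure. Nucleotide-level
work (ORF calling, database homology search) is out of scope; inputs are
protein FASTA or the translations in a GenBank record.

## Domain detection

Each domain type (KS, AT, DH, ER, KR, ACP, TE) has one packaged exemplar
sequence. Candidate windows are the local alignments (BLOSUM62, gap open
−11, extend −1) of an exemplar against the query protein scoring at least
`window_threshold` × the exemplar self-score; all disjoint above-threshold
windows are found by divide-and-conquer around the best hit. Overlaps
between candidates of different types are resolved greedily by descending
score, ties by leftmost start, so output is deterministic. Each window is
then validated by scanning the domain's catalytic motifs (degenerate
patterns with fixed letters, `x` wildcards, `/` alternatives, `(x)`
optional positions, and a per-motif mismatch budget — 0 for catalytic
triads and short motifs, 1 for the long ER motif) and by reading the
catalytic residues located through the anchoring alignment. A hit failing
any check is kept but marked inactive with explicit reasons. KS windows
whose catalytic position holds Gln are re-typed KSq (the decarboxylating
loading variant); Cys marks a condensing KS; anything else is inactive.

`window_threshold` defaults to 0.35. The value has to be explicit because
domain boundaries are defined operationally by exemplar alignment; at 0.35
a window survives substitution noise well above any realistic drift (a 45%
mutated exemplar still anchors) while random 100–130-aa sequence scores
about an order of magnitude below threshold.

## Functional classification

**AT specificity.** Two routes. (1) Residues: the query is globally aligned
to the panel anchor; the residues aligned to the four
specificity-determining columns are majority-voted against the per-class
expectations (HAFH for malonyl-CoA, YASH for methylmalonyl-CoA, following
the published key-residue convention). Confidence is the fraction of
readable columns agreeing with the winner; a tie or >50% gapped columns
yields `unknown`. (2) Phylogeny: progressive MSA of query + panel,
p-distances, neighbor joining, bootstrap; the call is the class of the
smallest monophyletic reference clade containing the query, its support
the bootstrap percentage of that clade's branch. When the two routes
disagree, a configurable precedence (default: residues) decides the
reported specificity and the call is flagged discordant with both
evidences retained — this mirrors how the RDM loading AT0 is handled: the
backbone-consistent call is used while the phylogenetic anomaly stays on
record.

**KR stereo-type.** Diagnostic positions are defined relative to the
packaged KR exemplar (alignment-mapped, not absolute offsets, for
robustness to indels): a three-residue B-type window read as LDD or LED
implies a B-type KR and an *R*-configured alcohol; Trp at the A-type
position implies A-type and *S*; neither leaves the module `unassigned`
with an `unknown` hydroxyl configuration — the prediction never guesses a
configuration without a signature, and both signatures at once is reported
as a conflict, not resolved. Exact diagnostic coordinates in real KRs
(Caffrey-style) live in the editable sidecar TSV rather than code.

**DH/ER.** A DH is functional iff its HxxxGxxxP consensus is intact; ER
presence requires an intact LxHxxxGGVGxxAxxxA. Both are module-level
booleans consumed by the chemotype rules.

## Module partitioning

Modules are cut at each KS/KSq; domains up to the next KS belong to the
left module; ORF order is explicit. The grammar
KS–AT–[DH–[ER–]][KR–]ACP is checked and violations are logged on the
module, never fatal; domains preceding the first KS of the line attach to
the loading module with a violation note. No KS at all is an error.

## Colinearity rules

With N extension modules the backbone has 2(N+1) carbons, C1 being the
TE-bound carbonyl (matching the C-13…C-23 / Δ2…Δ28 numbering convention of
polyene macrolides). Module m (1…N):

* β-carbon = 2N+3−2m. KR A-type → S-OH, B-type → R-OH, unassigned →
  OH of unknown configuration, no/inactive KR → ketone.
* functional DH on an R-OH → E-double bond Δ(2N+2−2m), consuming the OH;
  DH over an S/unknown OH is flagged and draws no bond (the model only
  performs syn elimination on R-configured intermediates); DH without KR is
  flagged and the ketone kept; DH+ER → methylene.
* methylmalonyl AT → methyl branch at 2N+2−2m.
* a methylmalonyl loading AT means a propionate starter after KSq
  decarboxylation, acetate otherwise.

These closed-form positions are tested exhaustively against an independent
unit-by-unit chain-growth oracle for all N ≤ 20.

Reconciliation compares starter unit, methyl-branch set, per-position OH
presence/configuration (unknown configurations match anything) and the
double-bond set, mapping each mismatch to the responsible module. A
predicted double bond standing where the observed structure has a hydroxyl
(or vice versa) is one DH-level disagreement, not two — which is exactly
how the "skipped" DH of RDM module 2 surfaces. DH skips are never inferred
during prediction; they are produced by reconciliation and can then be
applied as overrides to regenerate the final chemotype, reproducing the
predict → compare → annotate order of the original analysis. Carbon-count
disagreement short-circuits to a single fatal discrepancy. The macrolactone
ring-closure position is left unset by default because the lactonization
hydroxyl is a structure-level fact the sequence analysis does not
determine. Z-configured double bonds are out of model (attributable to
post-assembly isomerization). `titer_fold_change` is the small arithmetic
utility for comparing reported production means (two decimals).

## Alignment and phylogeny

The global pairwise aligner is a Gotoh affine-gap DP (BLOSUM62, open −11,
extend −1, Biopython gap convention) with a deterministic traceback
(diagonal > up > left on ties); its scores are cross-checked in tests
against an independent aligner. The progressive MSA builds a UPGMA guide
tree from pairwise p-distances and merges profiles in guide order, scoring
column pairs by expected substitution score (frequency-weighted), gaps
scoring zero. Distances are p-distances with pairwise gap deletion — the
simplest defensible default where no model is stated; the distance function
is injectable. Neighbor joining uses the Q-criterion with ties broken by
the lexicographically smallest label pair (internal nodes inherit the
smallest leaf label beneath them); the final three nodes are resolved by
the three-point formulas. Negative NJ branch lengths are clamped to zero
for display with the raw value retained on the node. Bootstrap resamples
alignment columns with replacement; the support of each original-tree
bipartition is the percentage of replicate trees containing it, exactly
count/n. All randomness flows from one caller-supplied seed. Default
bootstrap depth is 1000 replicates (seconds on a 20-taxon, 300-column
alignment); classification-time placements in tests use 3–10 replicates
since only the topology decides the class.

## Synthetic data

The generator emulates multi-ORF assembly-line proteins: per-domain
exemplar scaffolds joined by a neutral linker, with class-determining
residues injected (KSq Gln, AT specificity block and class-consensus
background, KR LDD/LED/Trp) and seeded per-residue substitution noise that
avoids the annotated diagnostic/motif sites unless corruption of a named
site is requested. Scaffolds and the AT panel are synthetic consensus-like
sequences designed for this package (not database entries), shipped as
small text data files with a sidecar site table; AT panel members carry 16
class-level background differences plus 4 member-specific substitutions, so
within-class p-distance (~7%) is well below between-class (~17%).

The packaged fixture encodes the Rdm assembly line itself: 17 modules over
RdmG (loading + 1–2), RdmH (3–6), RdmI (7–12), RdmJ (13–16 + TE);
methylmalonyl ATs 0–2 (AT0 flagged discordant), malonyl 3–16; B-type KRs
{1,2,3,12,13,14} (LDD) and {15,16} (LED), A-type {6,7,9,10,11}, unassigned
{4,5,8}; functional DHs {1,2,3,12,13,14,15,16}; ER only in module 1. The
observed RDM A chemotype is encoded with exactly the published facts; the
configuration of the module-2 hydroxyl retained under the DH skip, and any
detail available only from the structure figure, are encoded `unknown`
rather than invented.

What the synthetic data does not emulate: real inter-domain linker
diversity, domain-boundary ambiguity, insertions/deletions, docking
domains, and DNA-level features. Passing the zero-noise round trip
therefore demonstrates internal consistency of detection + classification +
prediction, not detector performance on natural sequences; the noise sweep
(recovery non-increasing in substitution rate) probes robustness only to
point substitutions.

## Problem sizes and determinism

The test suite and acceptance script run on the fixture-scale problems the
analysis itself uses: four ORFs of 1.7–3.2 k residues, an 8-member AT
panel, trees up to 20 taxa, bootstrap up to 1000 replicates, 100-replicate
noisy-AT recovery. Identical seeds give byte-identical generator output and
identical bootstrap supports.

## Known limitations

* Domain boundaries are operational (exemplar alignment), not curated;
  real-sequence use should treat interval edges as approximate.
* The AT residue table covers the malonyl/methylmalonyl dichotomy only;
  other extenders (ethylmalonyl, methoxymalonyl) report as the nearest of
  the two or `unknown`.
* Trans-AT systems, MT/Cy/Ox domains, and iterative module use break the
  one-module-one-extension assumption and are not modeled.
* The phylogeny is NJ on p-distances; it is a placement heuristic, not a
  model-based inference, and supports on very short regions are
  accordingly coarse.
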