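# Methods

This note records the modelling choices behind the package: the procedure,
its assumptions, the parameters that matter, what the synthetic fixture does
and does not emulate, and the numerical conventions.

## Hypotheses and the reference dataset

A hypothesis is any object implementing three clauses: scope matching,
domain matching, and a symmetric similarity index in [0, 1]. Four kinds are
provided: the universal root, structural hypotheses (fragment
conjunctions), property-range hypotheses (a computed property inside a
closed interval), and example hypotheses (one per distinct observed
structure). Coverage and signal are always relative to a fixed reference
dataset; the package assumes binary labels throughout. The signal
`S_y = (2·n_y − N)/N` is undefined at `N = 0`, so hypotheses with empty
coverage are rejected at network insertion rather than carrying an
undefined value.

Duplicate structures are indistinguishable to every contract clause, so
duplicated examples collapse into a single example node carrying all their
ids. Dataset curation (`dedup_policy`) defaults to `drop-conflicts`:
structures whose copies disagree on the label are removed, consistent
duplicates keep their first copy. Conflicting duplicates are almost always
measurement or transcription noise, and keeping them both plants
irreducible error in exact-match predictions.

## Fragmentation and the applicability domain

Molecules are parsed and sanitised once (RDKit's default aromaticity
model); all matching runs on the sanitised graph. Salts keep the largest
component by heavy-atom count. The reduced graph collapses fused ring
systems (rings sharing at least one atom) into single units, then matches a
fixed functional-group SMARTS table greedily in order (nitro, nitroso,
sulfonic acid, sulfonyl, carboxylic acid, cyano, carbonyl, amine, hydroxyl,
ether oxygen) on the remaining non-ring atoms; whatever is left becomes
single-atom units. Halogens deliberately stay atomic; three-membered
heterocycles (epoxide, aziridine) are ring systems. The table reproduces
the intended unit boundaries for the classic mutagenicity motifs without
attempting a complete functional-group ontology.

Fragments are unit paths of 1..`max_path_len` units (default 3) plus each
unit's neighbourhood of radius `circular_radius` (default 1), expanded back
to molecular fragments. Attachment points are retained for display (`*` in
the pattern) but ignored for matching: fragment queries are open
substructures. A parsing detail worth recording: re-parsing a fragment's
SMILES can assign radical electrons to under-coordinated charged atoms
(e.g. the nitrogen of an unattached nitro group), and radicals participate
in RDKit substructure matching; queries therefore clear radical counts,
since open valences mean attachment, not radicals.

Dictionary support counts *examples containing the fragment* (by
substructure match, not enumeration provenance, so support is consistent
with hypothesis coverage). `min_support` = 4 separates "non-rare" fragments.
The structural applicability domain requires every heavy atom **and** every
bond of a query to lie inside at least one match of a non-rare fragment;
the report lists uncovered atoms/bonds. Unusual training examples can
legitimately fall outside the domain if all fragments spanning one of their
bonds are rare.

## Mining

Non-rare fragments become boolean presence descriptors. A decision tree
maximising Shannon information gain (base 2) is grown with stopping rules:
purity, node size < `min_node_size` (4), depth ≥ `max_depth` (8), or best
gain below `min_gain` (0) — a zero-gain split carries no information and is
never made. Gain ties break on the lexicographically smaller fragment key,
making the tree a pure function of its inputs.

Every node reached through at least one presence edge emits a structural
hypothesis whose conjunction is the presence fragments on its path; nodes
reached only through absence edges emit nothing. "Fragment absent" is not
an interpretable structural alert, and the presence-path convention is what
guarantees each emitted child covers a subset of its emitting ancestor. An
alternative `node` emission mode (last split fragment only) is available
behind `emit_mode`. Emitted hypotheses are filtered on `min_coverage` (4)
and `min_abs_signal` (0), de-duplicating identical coverages in favour of
the shortest conjunction.

## Network organisation

The network stores the transitive reduction (Hasse diagram) of the strict
coverage-subset order; hypotheses with identical coverage are incomparable
siblings. Incremental insertion links a new node below its minimal strict
supersets and above its maximal strict subsets and deletes the
parent→child edges that become transitive; removal re-links grandparents
to grandchildren where no remaining node sits strictly between. Both are
verified in the tests against a brute-force reconstruction, which also
establishes insertion-order independence. The structure is a DAG, not a
tree: a specific hypothesis may have several incomparable parents.

## Prediction

The relevant hypotheses for a query are the matching, in-domain nodes with
no matching in-domain strict descendant. The implementation filters all
nodes and removes those with an eligible descendant (reachability in a
transitive reduction equals the order itself); hypotheses that match but
fail the domain clause are skipped without blocking their descendants. The
root matches everything, so the result is never empty, and a query
identical to a reference structure resolves to that example node alone.

Local predictions take the k (default 10) most similar supporting examples
(ties at the k-th rank broken by example id), weight them by
√similarity (`similarity_exponent` = 0.5), and divide the weighted signal
sum by **k**, not by the number of neighbours found: thin or distant
support shrinks the signal toward equivocal, which is the intended
confidence semantics (`divide_by_k_used` restores the plain weighted mean).
Example hypotheses short-circuit to the factual data — an exact match is
certain, confidence 1 — rather than being diluted by the k divisor. A local
call whose sign contradicts the hypothesis's own reference signal is
flagged *overruled*; overruled locals stay in the overall call by default
(they carry real local evidence) and can be dropped with
`ignore_overruled`.

The overall signal is the confidence-weighted mean of local signals,
classified against the band `a ± b`; if every retained confidence is 0 the
call is equivocal with signal 0. Raising `b` can only move class calls into
the equivocal band, never the reverse.

## Confidence standardisation

Cross-validated predictions are pooled into 5 equidistant raw-confidence
bins; bin accuracy (over non-equivocal calls) is fitted by a weighted
least-squares polynomial of order min(3, bins−1) in the bin's mean raw
confidence. The standard confidence anchors this fit with the affine map
`2·accuracy − 1`, so coin-flip accuracy maps to 0 and perfect accuracy to
1, clipped to [0, 1] and made non-decreasing by isotonic projection
(cumulative maximum on a 201-point grid, linear interpolation in between).
Fewer than 3 non-empty bins fall back to the identity transform with a
warning. Whether the original polynomial maps raw confidence to accuracy
or to the standard scale directly is an open choice; anchoring through
accuracy makes both recoverable.

## Cross-validation

Stratified, seeded k-fold (default 5). The fragment dictionary, descriptor
matrix, tree and network are rebuilt from the training folds only; the
test fold never influences descriptors, supports or splits (audited by the
leakage test via `fold_details`). Metrics exclude equivocal predictions
from the confusion matrix by default and report them separately; undefined
ratios (empty denominators) are reported as undefined rather than 0.

## The synthetic fixture

The generator assembles molecules from 10 scaffolds (8 aromatic, 2
saturated) and 16 decorations, then labels them by planted rules: aromatic
nitro, aromatic primary amine, epoxide and aziridine activate; a sulfonate
meta to an aromatic nitro group mitigates. Labels flip independently with
probability `noise`. Design choices, fixed once:

- Nitro decorates ~65% of aromatic scaffolds. The prevalence is far above
  any real screening library; it is chosen so the planted alert's signal is
  estimable with small sampling error from a 500-molecule dataset.
- The mitigated combination (benzene + nitro + meta sulfonate, nothing
  else) is a distinct component at 2%, so the mitigated subclass has
  enough support to be minable while barely diluting the alert; outside
  this component nitro and sulfonate never co-occur, keeping the
  mitigation clean.
- Nitro and amine attach only to aromatic scaffolds (arene chemistry), so
  the planted SMARTS rules and the mined nitro fragment agree on scope.

What the fixture does **not** emulate: realistic chemical diversity (a few
hundred distinct cores at most), activity cliffs other than the planted
mitigation, assay-dependent noise structure, class imbalance beyond what
the rules induce, or fragments at real-data scale (hundreds of distinct
fragments versus tens of thousands). Passing tests therefore demonstrate
that the machinery recovers and organises planted knowledge under noise,
not that the default configuration transfers to any particular assay.

## Problem sizes and numerics

The test suite and acceptance checks run at deliberately modest sizes —
datasets of 30–500 molecules, networks up to a few hundred nodes, 200
randomised trials for the order/search oracles, 10,000 random neighbour
sets for the local-signal identity — chosen as the smallest scales at which
each property is non-trivially exercised. Floating-point identities are
asserted at 1e−12; gain ties are compared within 1e−12 before the
lexicographic tie-break; the calibration grid has step 0.005. Molecule
canonicalisation, fingerprints (linear paths to 7 bonds, 2048 bits) and
substructure matching are delegated to RDKit; graph storage and
reachability to networkx; fold assignment to scikit-learn.

## Known limitations

- Binary endpoints only; the signal formalism generalises to L > 2 but no
  downstream component consumes it.
- Similarity-threshold and pharmacophore hypotheses fit the contract but
  are not implemented; property-range hypotheses are a minimal
  demonstrator over a small registry of computed properties.
- Stereochemistry and tautomerism are not normalised beyond RDKit
  canonicalisation; enantiomers with distinct SMILES are distinct
  structures.
- The incremental Hasse update is quadratic in network size per insertion;
  at the intended scale (hundreds to a few thousand nodes) this is
  negligible, but million-node networks would need the batch construction.
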