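# sohn — self-organising hypothesis networks for SAR classification

`sohn` builds interpretable binary structure–activity (SAR) classifiers for
molecular endpoints such as mutagenicity. Instead of a single opaque model,
it mines a collection of **hypotheses** — small, human-readable knowledge
units such as "contains an aromatic nitro group" — and organises them into a
network ordered from the most general to the most specific. Predictions come
with the hypotheses that produced them, the reference examples supporting
each hypothesis, and a calibrated confidence, so a chemist or toxicologist
can audit every call.

## The model

A *hypothesis* `h` implements three clauses: scope matching (does `h` apply
to structure `s`?), domain matching (can `h` be reliably evaluated for
`s`?), and a normalised similarity index between structures. Relative to a
reference dataset `D` with classes `Y` (|Y| = L = 2 here), each hypothesis
has

- a **coverage** `C(h, D)` — the covered examples, with `N = |C(h, D)|`, and
- a per-class **signal** `S_y(h, D) = (L·n_y − N) / ((L−1)·N)`,

which is 1 when the coverage is pure class *y* and 0 when *y* sits at its
balanced share. Hypotheses are ordered by generality — `h1 > h2` iff
`C(h2, D) ⊊ C(h1, D)` — and stored as the transitive reduction of this
partial order (a Hasse diagram): the universal root `h0` on top, one
example hypothesis per observed structure at the bottom. The network shape
is independent of insertion order.

Structural hypotheses are conjunctions of fragments produced by a
reduced-graph fragmentation (ring systems, functional groups and atoms as
units; linear unit paths plus circular neighbourhoods, expanded back to
molecular fragments). They are mined with a small decision tree on
fragment-presence descriptors and filtered on coverage and signal.

To predict a query `x`, the network is searched for the most specific
matching, in-domain hypotheses. Each relevant hypothesis makes a local kNN
call over its supporting examples (k = 10):

```
w_i = √Similarity(x, e_i)          s_i ∈ {−1, +1}
S_h,x = Σ w_i·s_i / k              class = sign, confidence = |S_h,x|
```

and the overall signal weights each local call by its confidence,
`s_x = Σ S_h·conf_h / Σ conf_h`, classified against the band `a ± b`
(defaults 0, 0). Raw confidence `|s_x|` is mapped to a **standard
confidence** tracking expected accuracy via an order-3 polynomial fitted to
binned confidence-vs-accuracy from cross-validation. The applicability
domain requires every atom and bond of the query to be covered by a
dictionary fragment supported by at least 4 reference examples.

No external data are needed: a seeded generator plants SAR rules (aromatic
nitro → active, aromatic amine → active, sulfonate *meta* to the nitro
group → mitigated) into grammar-built molecules, so the whole pipeline is
testable offline.

## Worked example

```
$ sohn simulate -n 300 --seed 1 --noise 0.05 -o train.csv
wrote 300 examples to train.csv
$ sohn build -d train.csv -o sohn_model.json
model: 16 hypotheses, 276 network nodes -> sohn_model.json
$ sohn predict -m sohn_model.json \
    -q "O=[N+]([O-])c1ccc(CC)cc1" \
    -q "O=S(=O)(O)c1cccc([N+](=O)[O-])c1"
query: query0
class: POSITIVE
standard confidence: 0.444
hypotheses used (m=1):
  m008: POSITIVE (confidence 0.444) - *N AND *[N+](=O)[O-] AND ...
    support syn0169 similarity 0.537 (-)
    support syn0247 similarity 0.517 (+)
    ...
    path: h0 -> m000 -> m012 -> m001 -> m002 -> m008

query: query1
class: NEGATIVE
standard confidence: 1.000
hypotheses used (m=1):
  ex:syn0049: NEGATIVE (confidence 1.000) - example syn0049 (NEGATIVE)
    support syn0049 similarity 1.000 (-)
```

The first query (an aromatic nitro compound) is called POSITIVE through a
mined structural hypothesis; the listed supporting examples are its nearest
neighbours with their similarities, and the path from `h0` explains which
refinements led there. The second query carries the planted mitigation
(sulfonate meta to the nitro group): it is an exact match of a reference
example, so the call is its observed class with confidence 1.

`sohn validate -d train.csv` runs 5-fold cross-validation and writes the
confusion metrics (BAC/SEN/SPEC/PPV/NPV), the hypothesis-count
distribution, and the fitted calibration model; `sohn export-dot` renders
the network for graphviz.

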