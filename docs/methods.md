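# Methods

## Model

`biotrans` treats microbial biotransformation as iterated application of
generalized reaction rules. A rule is a SMIRKS transform: its left-hand
side is a substructure pattern describing a functional group, its
right-hand side the transformed group, linked by atom maps. A rule
*triggers* on a compound when the pattern has at least one substructure
match; applying it yields one *product set* per distinct match (a single
transformation event can give several co-products, as in hydrolyses).
RDKit supplies the SMILES/SMARTS/SMIRKS machinery; this package adds the
conventions that make iterated application well behaved:

* compounds are identified by canonical SMILES, with multi-fragment
  structures canonicalized fragment-wise and sorted-joined so fragment
  order never matters;
* product sets are deduplicated across symmetric matches by their sorted
  canonical product SMILES;
* products failing valence sanitization are dropped with a warning —
  general rules occasionally produce impossible chemistry, and one bad
  match must not abort a prediction;
* stereochemistry is preserved where a SMIRKS is silent and overwritten
  where it is explicit; the fixture rules avoid stereocenters so their
  oracles stay simple;
* explicit-hydrogen atom maps in SMIRKS are honored, products are returned
  with implicit hydrogens.

Pathway prediction is breadth-first and level-synchronous: level 0 is the
root compound; at each level every not-yet-expanded node is expanded with
all rules from the selected packages, and each genuinely new product
becomes a node of the next level. Re-deriving a known compound through a
different rule adds a parallel edge; a product identical to an ancestor
adds a back-edge, and no node is ever expanded twice — together with the
depth and product caps this guarantees termination even for rule sets that
trigger on their own products.

Stopping criteria: no new products, a depth limit (`max_levels`, default
4 — a library choice; shallow enough to read, deep enough to reach
terminal mineralization products of the toy chemistry), or a cap on
predicted products (`max_products`, default 50, the anonymous-tier limit;
counted as unique non-root compounds, since deduplication makes unique
nodes the natural unit). At the cap boundary, candidates are admitted in
deterministic order (score, then rule id, then product SMILES) until the
cap is exactly reached; a candidate whose products would cross it is
skipped, later smaller candidates may still fit, and the pathway is
annotated `capped`. Predictions are bit-reproducible for fixed (root,
settings, seed): every iteration order is explicitly sorted.

## Truncation strategies

**Likelihood filtering.** Each rule carries one of exactly five expert
categories of aerobic likelihood, ordered Very Likely > Likely > Neutral >
Unlikely > Very Unlikely; filtering keeps rules at or above a threshold
and is monotone in the threshold by construction.

**Suppression meta-rules.** A meta-rule names a winner and losers: if the
winner is applicable to a compound, candidates from the losers are
removed. Application iterates over per-pass snapshots to a fixed point, so
chains (A beats B, B beats C, all present) collapse in one call, and the
operation is idempotent. Suppression cycles among co-triggered rules are
detected via strongly connected components; their edges are disabled with
a warning and the involved rules retained — dropping both sides of an
inconsistent expert constraint would silently lose chemistry.

**ML relative reasoning.** Training data come from packages treated as
ground truth. One instance per unique educt compound in the packages'
reactions; its label vector marks, among the rules that trigger on it,
those whose predicted product multiset equals the products of some stored
reaction with that educt. Triggered-but-unobserved rules are negatives;
rules that do not trigger contribute no loss at all (labels are masked,
never imputed — only a predicted reaction can be called false). Features
are the concatenation of the triggered-rule indicator vector (the
"relative" part: a rule's fate may depend on its competitors) and a
1024-bit radius-2 hashed circular fingerprint. The reference learner is
L2-regularized logistic regression (C = 1): independently per rule in
single-label mode, as a one-vs-rest pass over the label matrix with shared
features in multi-label mode — with masked per-label fits these coincide
numerically, and the mode is recorded for interface compatibility;
label-dependency learners such as classifier chains are deliberately out
of scope. A rule whose triggered instances are single-class falls back to
the Laplace-smoothed constant (k+1)/(n+2); a rule never triggered in
training scores the zero-count constant 0.5; a rule entirely unknown to a
model scores the global prior (mean positive rate) with a warning. Models
serialize to versioned JSON (weights, rule order, feature config) and are
scored by a plain sigmoid over the stored weights, so no pickled estimator
ever ships. Observation is defined by product identity, not by generating
rule — two rules predicting identical products on the same educt are
indistinguishable in the ground truth, which matters for experiment design
(below). No probability calibration step is applied.

## Data model

Packages contain compounds, rules, reactions, pathways, scenarios and
half-life annotations, addressed by URI-like ids
`pkg/<uuid>/<type>/<uuid>` minted deterministically from a per-store
counter (identical build sequences give byte-identical exports). The store
is in-process, persisted as canonical JSON (sorted keys), validated on
import by a pydantic schema that reports JSON paths. Permissions are
reduced to owner, public/private visibility and a reviewer set: packages
start unreviewed, an owner submits (idempotent), a reviewer approves, and
a reviewed package accepts mutations only from reviewers. Anonymous-owned
packages strictly older than the retention window (default 30 days,
injectable clock) are purged; registered users' data never are. Half-life
annotations tie a compound, a pathway and a scenario to a positive value
in hours or days; they are stored and round-tripped but never used
predictively — persistence prediction is out of scope.

## Synthetic data

The fixture generator stands in for curated pathway collections. The toy
library holds eight hand-validated rules (alcohol→aldehyde, aldehyde→acid,
ester hydrolysis, amide hydrolysis, aromatic hydroxylation, N- and
O-demethylation, aromatic nitro reduction) spanning all five likelihood
categories; assignments loosely follow aerobic plausibility (nitro
reduction, favoured anaerobically, is the Very Unlikely exemplar). Roots
are ~20 hard-coded small molecules chosen to trigger every rule — random
SMILES generation would guarantee neither triggering nor validity.

A synthetic package applies a chosen *active subset* of rules (default 4
of 8: the alcohol oxidation chain, ester hydrolysis, O-demethylation) to
the roots up to 3 levels, omitting each reaction with probability
`noise_rate` (default 0.1) to emulate curation gaps, and attaches a soil
scenario with per-root half-lives drawn log-uniformly from 1–100 days.
The default active subset keeps ester hydrolysis and O-demethylation on
the same side of the active/inactive split: both cleave methyl esters to
acid + methanol, so splitting them would make the ground-truth labels
ambiguous by construction. The explosion ruleset (four substituent
additions on aliphatic C–H) grows from ethane by 4, 20, 70 new unique
products per level — past the 50 cap by level 3 — for testing the
stopping criteria.

What passing on this data does *not* show: real rule libraries are far
larger and their triggering patterns far more correlated; real packages
contain conflicting, condition-dependent evidence; and the synthetic
generator's chemistry is, by design, exactly expressible by the rule
vocabulary. Recovery of the active subset demonstrates the learning
machinery is sound, not that the models transfer to environmental data.

## Evaluation

The built-in recovery experiment generates a synthetic package, splits its
training instances 70/30, trains on the 70 % and compares mean held-out
scores of active vs inactive rules. With ~13–16 instances per package, a
held-out split may contain no compound triggering any inactive rule; such
runs yield no rankable pairs, and aggregate accuracies pool pair counts
across seeds. The acceptance script runs 5 seeds per mode; sizes (20
roots, 3 levels, 8 rules) keep the whole evaluation under a few seconds
while leaving enough instances for the separation to be non-trivial.

## Known limitations

* Only single-educt rules are executable; multi-reactant SMIRKS parse but
  never trigger (logged). Biotransformation rules are conventionally
  single-substrate.
* Composite rules (`composite_members`) are stored and round-tripped but
  not expanded into their members during prediction.
* The wrapper and its test oracle both ultimately drive RDKit; the oracle
  is a separate, minimal direct path (no dedup/fragment/drop logic), so it
  checks the package's conventions, not RDKit itself.
* Tautomers, protonation states and 3D structure are out of scope;
  compounds differing only in those respects are distinct nodes.
* Concurrency is modeled as a status field (`in_progress` → `completed`)
  with a progress hook; the library runs synchronously.
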