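# biotrans

Rule-based prediction of microbial biotransformation pathways for organic
contaminants, with relative-reasoning strategies to control combinatorial
explosion.

When a xenobiotic chemical — a pesticide, a pharmaceutical, an industrial
solvent — enters soil, sludge or surface water, microbial communities
transform it step by step into transformation products (TPs). Knowing the
likely TPs matters for chemical risk assessment and environmental
monitoring, but measuring every pathway is infeasible. `biotrans` predicts
them: it encodes enzymatic transformations as generalized *biotransformation
rules* (SMIRKS transforms whose left-hand side matches a functional group),
applies every rule of a selected package to a parent compound, then applies
the rules again to each product, level by level, growing a pathway graph.

Because the rules must stay general they trigger promiscuously, and naive
iteration explodes combinatorially. Three truncation strategies prune the
candidates at every node:

* **aerobic likelihood** — each rule carries one of five expert categories
  (Very Likely > Likely > Neutral > Unlikely > Very Unlikely); keep rules at
  or above a threshold;
* **suppression meta-rules** — *relative* reasoning: whether a rule may fire
  depends on which other rules are simultaneously applicable (winner/loser
  pairs applied to a fixed point);
* **machine-learning relative reasoning** — a model trained on a *package*
  of curated pathways treated as ground truth. For each educt compound `x`
  and rule `r` that triggers on it, the model estimates
  `P(r observed | x, triggered rules)` from a feature vector of
  triggered-rule indicators plus a 1024-bit circular fingerprint; reactions
  the rules predict but the package does not contain count as negatives.
  Single-label mode fits one regularized logistic regression per rule;
  multi-label mode fits a one-vs-rest weight matrix over the shared features.

Data are organized in *packages* — compounds, rules, reactions, pathways,
scenarios (experimental conditions, optionally with biotransformation
half-lives) — which are the units of sharing, review (reviewed packages are
locked to reviewers) and ML training. Everything serializes to
deterministic JSON; anonymous-owned data are purged after 30 days, and
anonymous predictions are capped at 50 products.

## Worked example

```python
import biotrans as bt
from biotrans.fixtures import toy_rule_library

rules = toy_rule_library()          # 8 hand-validated SMIRKS rules
pathway = bt.predict("CCOC(C)=O",   # ethyl acetate
                     bt.PredictionSettings(max_levels=2),
                     bt.Store(), rules=rules)
print("nodes:", sorted(pathway.nodes))
for e in pathway.edges:
    print(f"{e.educt}  --[{e.rule_id}]-->  {' + '.join(e.products)}")
print("products:", pathway.n_products, "status:", pathway.status)
```

prints

```
nodes: ['CC(=O)O', 'CC=O', 'CCO', 'CCOC(C)=O']
CCOC(C)=O  --[bt0003]-->  CC(=O)O + CCO
CCO  --[bt0001]-->  CC=O
products: 3 status: completed
```

Ethyl acetate is hydrolyzed (rule `bt0003`) to acetic acid `CC(=O)O` plus
ethanol `CCO`; at the second level ethanol is oxidized (rule `bt0001`) to
acetaldehyde `CC=O`. Three unique transformation products were predicted
and the prediction completed without hitting the 50-product cap.

The same run from the shell, plus training a relative-reasoning model on a
synthetic ground-truth package:

```sh
biotrans fixtures --out-dir demo --seed 0
biotrans predict "CCOC(C)=O" --rules demo/toy_rules.jsonl --max-levels 2 --out demo/pathway.json
# -> predicted 3 products on 2 levels
biotrans train --packages demo/synthetic_package.json --mode multi --seed 0 --out demo/model.json
# -> trained multi-label model on 13 instances
biotrans predict "CCOC(C)=O" --rules demo/toy_rules.jsonl --truncation ml:demo/model.json:0.5
```

See `biotrans --help` for the remaining subcommands (`package
{create,import,export,review,purge}`, `rule {validate,apply}`).

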