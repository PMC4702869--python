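"""Truncation strategies: the answer to combinatorial explosion.

General biotransformation rules trigger promiscuously, so iterated rule
application quickly predicts far more products than are environmentally
relevant.  Three strategies prune the candidate transformations at each
pathway node:

1. **Aerobic-likelihood filtering** — keep only rules whose expert-assigned
   category is at least as likely as a threshold.
2. **Rule-based relative reasoning** — suppression meta-rules: whether a
   rule may fire depends on which *other* rules are simultaneously
   applicable to the same compound.
3. **Machine-learning relative reasoning** — a model trained on packages
   treated as ground truth assigns each triggered rule a probability; the
   engine keeps transformations above a cutoff.  Reactions predicted by the
   rules but absent from the training packages count as negatives; rules
   that did not trigger on a compound contribute no loss at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.linear_model import LogisticRegression

from .chem import Compound, Likelihood, ProductSet, TransformationRule, apply_rule, triggers
from .datamodel import Package
from .errors import TrainingError, ValidationError

logger = logging.getLogger(__name__)

Candidate = tuple[TransformationRule, ProductSet]


# ---------------------------------------------------------------------------
# Strategy 1: aerobic-likelihood filtering
# ---------------------------------------------------------------------------

def likelihood_filter(
    candidates: list[Candidate], threshold: "str | Likelihood"
) -> list[Candidate]:
    """Keep candidates whose rule is at least as likely as ``threshold``.

    Monotone: a stricter threshold always yields a subset.  The weakest
    threshold (Very Unlikely) is the identity.
    """
    thr = Likelihood.from_string(threshold)
    return [(rule, ps) for rule, ps in candidates if rule.likelihood >= thr]


# ---------------------------------------------------------------------------
# Strategy 2: suppression meta-rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaRule:
    """If ``winner`` is applicable, transformations by ``losers`` are
    suppressed."""

    winner: str
    losers: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if self.winner in self.losers:
            raise ValidationError("a meta-rule winner cannot be among its losers")


def apply_meta_rules(
    candidates: list[Candidate], meta_rules: list[MetaRule]
) -> list[Candidate]:
    """Apply suppression meta-rules to a candidate list, to a fixed point.

    Each pass works on a snapshot of the surviving rule set: every meta-rule
    whose winner is present in the snapshot removes its losers, meta-rules
    processed in list order.  Passes repeat until nothing changes, so
    suppression chains (A beats B, B beats C) collapse in one call and the
    operation is idempotent.  Cyclic suppression among co-triggered rules
    (A beats B and B beats A, both present) is detected up front; those
    edges are disabled with a warning and both rules retained.
    """
    present = {rule.rule_id for rule, _ in candidates}

    graph = nx.DiGraph()
    graph.add_nodes_from(present)
    for mr in meta_rules:
        for loser in mr.losers:
            if mr.winner in present and loser in present:
                graph.add_edge(mr.winner, loser)
    disabled: set[tuple[str, str]] = set()
    for scc in nx.strongly_connected_components(graph):
        if len(scc) > 1:
            cyc_edges = {(u, v) for u, v in graph.edges if u in scc and v in scc}
            disabled |= cyc_edges
            logger.warning(
                "cyclic suppression among co-triggered rules %s; retaining all",
                sorted(scc),
            )

    while True:
        snapshot = frozenset(present)
        removals: set[str] = set()
        for mr in meta_rules:
            if mr.winner in snapshot:
                removals |= {
                    loser
                    for loser in mr.losers
                    if loser in snapshot and (mr.winner, loser) not in disabled
                }
        if not removals & present:
            break
        present -= removals

    return [(rule, ps) for rule, ps in candidates if rule.rule_id in present]


# ---------------------------------------------------------------------------
# Strategy 3: machine-learning relative reasoning
# ---------------------------------------------------------------------------

_FP_RADIUS = 2
_FP_BITS = 1024


@dataclass
class TrainingInstance:
    """One educt compound with its triggered and observed rule labels.

    ``observed ⊆ triggered``: only a rule that actually fired on the
    compound can be confirmed or refuted by the ground-truth package.
    """

    compound: Compound
    triggered: list[str]
    observed: list[str]
    features: np.ndarray
    #: rule order the indicator block of ``features`` was built over;
    #: constant across a training set and becomes the model's label space
    rule_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.observed) <= set(self.triggered):
            raise ValidationError("observed rules must be a subset of triggered rules")


def _fingerprint(compound: Compound, n_bits: int = _FP_BITS, radius: int = _FP_RADIUS) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    mol = Chem.MolFromSmiles(compound.smiles_canonical)
    return np.array(gen.GetFingerprint(mol), dtype=np.float64)


def featurize(
    compound: Compound, triggered: list[str], rule_ids: list[str],
    n_bits: int = _FP_BITS, radius: int = _FP_RADIUS,
) -> np.ndarray:
    """Feature vector: triggered-rule indicators ++ hashed circular fingerprint.

    The indicator block is what makes the reasoning *relative* — a rule's
    probability may depend on which other rules fire on the same compound;
    the fingerprint adds structural context.
    """
    indicator = np.zeros(len(rule_ids))
    trig = set(triggered)
    for j, rid in enumerate(rule_ids):
        if rid in trig:
            indicator[j] = 1.0
    return np.concatenate([indicator, _fingerprint(compound, n_bits, radius)])


def build_training_set(
    packages: list[Package], rules: list[TransformationRule]
) -> list[TrainingInstance]:
    """Derive labeled instances from packages treated as ground truth.

    One instance per unique educt compound occurring in the packages'
    reactions.  A triggered rule is *observed* (positive) when some package
    reaction with that educt has products equal, as a canonical-SMILES
    multiset, to one of the rule's predicted product sets; triggered but
    unobserved rules are negatives.  Compounds triggering no rule carry no
    signal and are excluded.
    """
    if not rules:
        raise ValidationError("rules must be non-empty")
    rule_ids = [r.rule_id for r in rules]

    # educt canonical SMILES -> (compound, set of observed product keys)
    educts: dict[str, tuple[Compound, set[tuple[str, ...]]]] = {}
    for pkg in packages:
        for rx in pkg.reactions.values():
            for educt_id in rx.educts:
                compound = pkg.compounds[educt_id]
                product_key = tuple(
                    sorted(pkg.compounds[pid].smiles_canonical for pid in rx.products)
                )
                entry = educts.setdefault(compound.smiles_canonical, (compound, set()))
                entry[1].add(product_key)

    if not educts:
        logger.warning("no reactions found in packages; empty training set")
        return []

    instances: list[TrainingInstance] = []
    for canonical in sorted(educts):
        compound, observed_keys = educts[canonical]
        triggered = [r.rule_id for r in rules if triggers(r, compound)]
        if not triggered:
            continue
        observed = []
        for rule in rules:
            if rule.rule_id not in triggered:
                continue
            predicted_keys = {ps.key for ps in apply_rule(rule, compound)}
            if predicted_keys & observed_keys:
                observed.append(rule.rule_id)
        instances.append(
            TrainingInstance(
                compound=compound,
                triggered=triggered,
                observed=observed,
                features=featurize(compound, triggered, rule_ids),
                rule_ids=rule_ids,
            )
        )
    if not instances:
        logger.warning("no educt triggered any rule; empty training set")
    return instances


@dataclass
class RelativeReasoningModel:
    """Probability scorer for (compound, rule) transformations.

    Per-rule scorers are either logistic models (weights over the shared
    feature space) or smoothed constants when training saw only one class.
    Serializes to versioned JSON — weights, rule order, feature config —
    never to binary pickles.
    """

    mode: str
    rule_ids: list[str]
    scorers: dict[str, dict]
    global_prior: float
    feature_config: dict = field(default_factory=lambda: {"n_bits": _FP_BITS, "radius": _FP_RADIUS})
    training_meta: dict = field(default_factory=dict)

    def score(self, compound: Compound, triggered_rules: list[str]) -> dict[str, float]:
        """Probability in [0, 1] for each triggered rule (deterministic)."""
        if not triggered_rules:
            return {}
        known = [rid for rid in triggered_rules if rid in self.scorers]
        x = featurize(
            compound, known, self.rule_ids,
            n_bits=self.feature_config["n_bits"], radius=self.feature_config["radius"],
        )
        out: dict[str, float] = {}
        for rid in triggered_rules:
            scorer = self.scorers.get(rid)
            if scorer is None:
                logger.warning("rule %s unknown to model; scoring with global prior", rid)
                out[rid] = self.global_prior
            elif scorer["kind"] == "constant":
                out[rid] = scorer["p"]
            else:
                z = float(np.dot(scorer["coef"], x)) + scorer["intercept"]
                out[rid] = 1.0 / (1.0 + math.exp(-z))
        return out

    def to_json(self) -> dict:
        def _clean(s: dict) -> dict:
            if s["kind"] == "logistic":
                return {"kind": "logistic", "coef": [float(c) for c in s["coef"]],
                        "intercept": float(s["intercept"])}
            return {"kind": "constant", "p": float(s["p"])}

        return {
            "schema_version": 1,
            "mode": self.mode,
            "rule_ids": self.rule_ids,
            "feature_config": self.feature_config,
            "global_prior": self.global_prior,
            "scorers": {rid: _clean(s) for rid, s in self.scorers.items()},
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "RelativeReasoningModel":
        scorers = {
            rid: (dict(s) if s["kind"] == "constant"
                  else {"kind": "logistic", "coef": np.asarray(s["coef"]),
                        "intercept": s["intercept"]})
            for rid, s in doc["scorers"].items()
        }
        return cls(
            mode=doc["mode"],
            rule_ids=list(doc["rule_ids"]),
            scorers=scorers,
            global_prior=doc["global_prior"],
            feature_config=dict(doc["feature_config"]),
            training_meta=dict(doc.get("training_meta", {})),
        )


MODES = ("single_label", "multi_label")


def train(
    training_set: list[TrainingInstance],
    mode: str = "multi_label",
    seed: int = 0,
    training_meta: dict | None = None,
) -> RelativeReasoningModel:
    """Fit a relative-reasoning model on a labeled training set.

    ``single_label`` fits an independent regularized logistic regression
    per rule; ``multi_label`` fits a one-vs-rest weight matrix over the
    shared feature matrix in one pass.  In both modes a rule's binary
    problem uses only the instances where that rule triggered — rules that
    did not fire contribute no loss (triggered-mask).  A rule whose
    triggered instances are single-class gets a Laplace-smoothed constant
    scorer ``(k + 1) / (n + 2)``.  Deterministic given ``seed``.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    if not training_set:
        raise TrainingError("cannot train on an empty training set")

    n_features = len(training_set[0].features)
    if any(len(inst.features) != n_features for inst in training_set):
        raise ValidationError("feature vectors must share a fixed length")

    # label space = the rule order the features were built over; falls back
    # to first-seen triggered order for hand-built instances
    rule_ids = list(training_set[0].rule_ids)
    if not rule_ids:
        for inst in training_set:
            for rid in inst.triggered:
                if rid not in rule_ids:
                    rule_ids.append(rid)

    X = np.vstack([inst.features for inst in training_set])
    n_pos_total = sum(len(inst.observed) for inst in training_set)
    n_trig_total = sum(len(inst.triggered) for inst in training_set)
    global_prior = (n_pos_total + 1) / (n_trig_total + 2)

    scorers: dict[str, dict] = {}
    for rid in rule_ids:
        mask = np.array([rid in inst.triggered for inst in training_set])
        if not mask.any():
            # never triggered in training: Laplace with zero counts -> 0.5
            scorers[rid] = {"kind": "constant", "p": 0.5}
            continue
        y = np.array([rid in inst.observed for inst in training_set])[mask]
        rows = X[mask]
        if len(np.unique(y)) < 2:
            scorers[rid] = {"kind": "constant", "p": (int(y.sum()) + 1) / (len(y) + 2)}
            continue
        clf = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
        clf.fit(rows, y)
        # orient coefficients toward the positive (True) class
        coef = clf.coef_[0] if clf.classes_[1] else -clf.coef_[0]
        intercept = clf.intercept_[0] if clf.classes_[1] else -clf.intercept_[0]
        scorers[rid] = {"kind": "logistic", "coef": coef, "intercept": float(intercept)}

    meta = dict(training_meta or {})
    meta.update({"seed": seed, "n_instances": len(training_set), "mode": mode})
    return RelativeReasoningModel(
        mode=mode,
        rule_ids=rule_ids,
        scorers=scorers,
        global_prior=global_prior,
        training_meta=meta,
    )


def score(
    model: RelativeReasoningModel, compound: Compound, triggered_rules: list[str]
) -> dict[str, float]:
    """Functional alias for :meth:`RelativeReasoningModel.score`."""
    return model.score(compound, triggered_rules)


# ---------------------------------------------------------------------------
# Strategy objects consumed by the prediction engine
# ---------------------------------------------------------------------------

ScoredCandidate = tuple[TransformationRule, ProductSet, float | None]


class TruncationStrategy:
    """Filters and scores candidate transformations at one pathway node."""

    name = "none"

    def apply(self, compound: Compound, candidates: list[Candidate]) -> list[ScoredCandidate]:
        return [(rule, ps, None) for rule, ps in candidates]


class NoTruncation(TruncationStrategy):
    pass


class LikelihoodTruncation(TruncationStrategy):
    name = "likelihood"

    def __init__(self, threshold: "str | Likelihood"):
        self.threshold = Likelihood.from_string(threshold)

    def apply(self, compound, candidates):
        kept = likelihood_filter(candidates, self.threshold)
        return [(rule, ps, rule.likelihood.rank / 4.0) for rule, ps in kept]


class MetaRuleTruncation(TruncationStrategy):
    name = "meta_rules"

    def __init__(self, meta_rules: list[MetaRule]):
        self.meta_rules = list(meta_rules)

    def apply(self, compound, candidates):
        kept = apply_meta_rules(candidates, self.meta_rules)
        return [(rule, ps, None) for rule, ps in kept]


class MLTruncation(TruncationStrategy):
    name = "ml"

    def __init__(self, model: RelativeReasoningModel, probability_cutoff: float = 0.5):
        if not 0.0 <= probability_cutoff <= 1.0:
            raise ValidationError("probability_cutoff must be in [0, 1]")
        self.model = model
        self.probability_cutoff = probability_cutoff

    def apply(self, compound, candidates):
        triggered = sorted({rule.rule_id for rule, _ in candidates})
        probs = self.model.score(compound, triggered)
        return [
            (rule, ps, probs[rule.rule_id])
            for rule, ps in candidates
            if probs[rule.rule_id] >= self.probability_cutoff
        ]
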