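"""Pathway prediction: iterated rule application with explosion control.

Starting from a root compound, every transformation rule from the selected
packages is applied; each product becomes a new pathway node and the rules
are applied again, level by level (breadth-first, level-synchronous), until
no new products appear, a depth limit is reached, or the total number of
predicted products hits a cap.  A pluggable truncation strategy
(:mod:`biotrans.reasoning`) prunes candidates at each node.

Pathways are directed multigraphs: re-deriving a known compound through a
different rule adds a parallel edge, never a duplicate node, and a product
equal to an ancestor adds a back-edge without re-expansion — this is what
makes termination certain even for self-feeding rule sets.

The pathway is stored in its target package the moment prediction starts
(status ``in_progress``) and flipped to ``completed`` at the end, mirroring
the asynchronous-feeling lifecycle without actual concurrency.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Callable

from .chem import Compound, TransformationRule, apply_rule, canonicalize
from .datamodel import Package, Reaction, Store
from .errors import ValidationError
from .reasoning import (
    NoTruncation,
    ScoredCandidate,
    TruncationStrategy,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEVELS = 4
DEFAULT_MAX_PRODUCTS = 50


@dataclass
class PathwayEdge:
    """One reaction edge: educt node → product nodes, via a rule."""

    educt: str                      # canonical SMILES of the educt node
    products: list[str]             # canonical SMILES of product nodes
    rule_id: str | None = None
    score: float | None = None
    reaction_id: str | None = None


@dataclass
class Pathway:
    """Directed graph of compound nodes (unique by canonical SMILES) and
    reaction edges, grown from a root."""

    root: Compound
    pathway_id: str | None = None
    nodes: dict[str, Compound] = field(default_factory=dict)
    edges: list[PathwayEdge] = field(default_factory=list)
    node_depth: dict[str, int] = field(default_factory=dict)
    status: str = "in_progress"
    provenance: str = "predicted"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.root.smiles_canonical not in self.nodes:
            self.nodes[self.root.smiles_canonical] = self.root
            self.node_depth[self.root.smiles_canonical] = 0

    @property
    def n_products(self) -> int:
        """Number of predicted product compounds (unique non-root nodes)."""
        return len(self.nodes) - 1

    def remove_node(self, canonical_smiles: str) -> None:
        """Remove a compound from this pathway (membership only — the
        compound entity in its package is untouched).  The root cannot be
        removed; incident edges disappear with the node."""
        if canonical_smiles == self.root.smiles_canonical:
            raise ValidationError("the root compound cannot be removed from a pathway")
        self.nodes.pop(canonical_smiles, None)
        self.node_depth.pop(canonical_smiles, None)
        self.edges = [
            e for e in self.edges
            if e.educt != canonical_smiles and canonical_smiles not in e.products
        ]

    def content_hash(self) -> str:
        """SHA-256 over the structural content (nodes, edges, status),
        independent of minted identifiers."""
        body = {
            "root": self.root.smiles_canonical,
            "nodes": sorted(self.nodes),
            "edges": sorted(
                (e.educt, e.rule_id or "", tuple(sorted(e.products)),
                 round(e.score, 12) if e.score is not None else None)
                for e in self.edges
            ),
            "status": self.status,
            "annotations": dict(sorted(self.annotations.items())),
        }
        return hashlib.sha256(
            json.dumps(body, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class PredictionSettings:
    """Knobs of one prediction run.

    ``max_products`` counts unique non-root compounds; 50 is the
    anonymous-tier default.  ``truncation`` is any
    :class:`~biotrans.reasoning.TruncationStrategy`.
    """

    max_levels: int = DEFAULT_MAX_LEVELS
    max_products: int = DEFAULT_MAX_PRODUCTS
    truncation: TruncationStrategy = field(default_factory=NoTruncation)
    packages: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_levels < 1:
            raise ValidationError("max_levels must be >= 1")
        if self.max_products < 1:
            raise ValidationError("max_products must be >= 1")


def expand_node(
    compound: Compound,
    rules: list[TransformationRule],
    strategy: TruncationStrategy | None = None,
) -> list[ScoredCandidate]:
    """Apply every rule to one compound and let the strategy prune/score.

    Output order is deterministic: descending score, then rule id, then the
    sorted product SMILES of the set.  An empty list marks a terminal
    compound.
    """
    if not rules:
        raise ValidationError("rules must be non-empty")
    strategy = strategy or NoTruncation()
    candidates = [
        (rule, ps)
        for rule in sorted(rules, key=lambda r: r.rule_id)
        for ps in apply_rule(rule, compound)
    ]
    scored = strategy.apply(compound, candidates)
    return sorted(
        scored,
        key=lambda c: (-(c[2] if c[2] is not None else 0.0), c[0].rule_id, c[1].key),
    )


def _collect_rules(store: Store, package_ids: list[str]) -> list[TransformationRule]:
    rules: dict[str, TransformationRule] = {}
    for pid in package_ids:
        pkg = store.get_package(pid)
        for rid, rule in pkg.rules.items():
            rules.setdefault(rid, rule)
    return [rules[rid] for rid in sorted(rules)]


def predict(
    root_smiles: str,
    settings: PredictionSettings,
    store: Store,
    target_package_id: str | None = None,
    rules: list[TransformationRule] | None = None,
    actor: str | None = None,
    progress_hook: Callable[[Pathway, int], None] | None = None,
) -> Pathway:
    """Predict a biotransformation pathway from a root SMILES.

    Level-synchronous breadth-first growth: at each level every
    not-yet-expanded node is expanded with all rules from the selected
    packages (or an explicit ``rules`` list).  Expansion halts when no new
    products appear, when ``max_levels`` is reached, or when adding a
    candidate's products would exceed ``max_products`` — candidates are
    admitted in deterministic order until the cap is exactly reached, a
    candidate that would cross it is skipped, and the pathway is annotated
    ``capped``.  Identical settings (including seed) give a bit-identical
    pathway.

    If ``target_package_id`` is given, the pathway (and its compounds,
    reactions) is stored there, immediately at start with status
    ``in_progress``, then flipped to ``completed``.
    """
    root = canonicalize(root_smiles)
    if rules is None:
        rules = _collect_rules(store, settings.packages)
    if not rules:
        raise ValidationError("no transformation rules available for prediction")

    pkg: Package | None = None
    pathway = Pathway(root=root)
    if target_package_id is not None:
        pkg = store.get_package(target_package_id)
        store.add_entity(target_package_id, pathway, actor=actor)
        store.add_entity(target_package_id, root, actor=actor)

    expanded: set[str] = set()
    frontier = [root.smiles_canonical]
    capped = False
    level = 0
    while frontier and level < settings.max_levels and not capped:
        level += 1
        next_frontier: list[str] = []
        for node_smiles in sorted(frontier):
            if node_smiles in expanded:
                continue
            expanded.add(node_smiles)
            compound = pathway.nodes[node_smiles]
            for rule, pset, score in expand_node(compound, rules, settings.truncation):
                new_products = [
                    c for c in pset.products if c.smiles_canonical not in pathway.nodes
                ]
                if pathway.n_products + len(new_products) > settings.max_products:
                    capped = True
                    continue  # skip the crossing candidate; a smaller one may fit
                for product in new_products:
                    pathway.nodes[product.smiles_canonical] = product
                    pathway.node_depth[product.smiles_canonical] = level
                    next_frontier.append(product.smiles_canonical)
                edge = PathwayEdge(
                    educt=node_smiles,
                    products=[c.smiles_canonical for c in pset.products],
                    rule_id=rule.rule_id,
                    score=score,
                )
                if pkg is not None:
                    educt_id = store.add_entity(pkg.package_id, compound, actor=actor)
                    product_ids = [
                        store.add_entity(pkg.package_id, c, actor=actor)
                        for c in pset.products
                    ]
                    rule_link = rule.rule_id if rule.rule_id in pkg.rules else None
                    edge.reaction_id = store.add_entity(
                        pkg.package_id,
                        Reaction(
                            educts=[educt_id],
                            products=product_ids,
                            rule_link=rule_link,
                        ),
                        actor=actor,
                    )
                pathway.edges.append(edge)
        frontier = next_frontier
        if progress_hook is not None:
            progress_hook(pathway, level)

    if capped:
        pathway.annotations["capped"] = True
    pathway.status = "completed"
    return pathway


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def pathway_to_dict(pathway: Pathway) -> dict:
    return {
        "pathway_id": pathway.pathway_id,
        "root": pathway.root.smiles_canonical,
        "nodes": [
            {
                "smiles": smiles,
                "display_name": compound.display_name,
                "depth": pathway.node_depth.get(smiles, 0),
            }
            for smiles, compound in sorted(pathway.nodes.items())
        ],
        "edges": [
            {
                "educt": e.educt,
                "products": e.products,
                "rule_id": e.rule_id,
                "score": e.score,
                "reaction_id": e.reaction_id,
            }
            for e in pathway.edges
        ],
        "status": pathway.status,
        "provenance": pathway.provenance,
        "annotations": pathway.annotations,
    }


def pathway_from_dict(doc: dict) -> Pathway:
    root = canonicalize(doc["root"])
    pathway = Pathway(
        root=root,
        pathway_id=doc.get("pathway_id"),
        status=doc.get("status", "completed"),
        provenance=doc.get("provenance", "predicted"),
        annotations=dict(doc.get("annotations", {})),
    )
    for node in doc["nodes"]:
        compound = canonicalize(node["smiles"], display_name=node.get("display_name"))
        pathway.nodes[compound.smiles_canonical] = compound
        pathway.node_depth[compound.smiles_canonical] = node.get("depth", 0)
    for e in doc["edges"]:
        pathway.edges.append(
            PathwayEdge(
                educt=e["educt"],
                products=list(e["products"]),
                rule_id=e.get("rule_id"),
                score=e.get("score"),
                reaction_id=e.get("reaction_id"),
            )
        )
    return pathway


def pathway_to_dot(pathway: Pathway) -> str:
    """Graphviz DOT rendering of a pathway (nodes labeled by SMILES)."""
    lines = ["digraph pathway {", "  rankdir=TB;"]
    index = {smiles: f"n{i}" for i, smiles in enumerate(sorted(pathway.nodes))}
    for smiles, nid in index.items():
        shape = "doubleoctagon" if smiles == pathway.root.smiles_canonical else "box"
        lines.append(f'  {nid} [label="{smiles}", shape={shape}];')
    for e in pathway.edges:
        label = e.rule_id or ""
        if e.score is not None:
            label += f" ({e.score:.2f})"
        for product in e.products:
            lines.append(f'  {index[e.educt]} -> {index[product]} [label="{label}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
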