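"""Deterministic toy chemistry for tests, demos and model training.

No external pathway database ships with this package, so everything the
other modules need — a hand-validated rule library, compounds that trigger
it, runaway rule sets for cap testing, and whole synthetic packages with
pathways, reactions, scenarios and half-lives — is generated here, seeded
and reproducible byte-for-byte.

The synthetic packages emulate the *shape* of curated biodegradation
pathway data (educt→product chains annotated with scenarios and
half-lives), not the chemical distribution of any real database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .chem import TransformationRule, canonicalize, parse_rule, triggers
from .datamodel import HalfLifeAnnotation, Package, Reaction, Scenario, Store
from .engine import Pathway, PathwayEdge
from .errors import GenerationError, ValidationError
from .chem import apply_rule

# ---------------------------------------------------------------------------
# Toy rule library: 8 common aerobic biotransformations.
# Likelihood categories span all five levels; the assignment is a fixture
# design choice loosely following aerobic plausibility (nitro reduction is
# the anaerobic-favoured exemplar, hence Very Unlikely).
# ---------------------------------------------------------------------------

_RULE_SPECS = [
    ("bt0001", "primary alcohol to aldehyde",
     "[CH2:1][OH:2]>>[CH1:1]=[O:2]", "Likely"),
    ("bt0002", "aldehyde to carboxylic acid",
     "[CH1:1]=[O:2]>>[C:1](=[O:2])[OH]", "Very Likely"),
    ("bt0003", "ester hydrolysis",
     "[C:1](=[O:2])[O:3][CX4:4]>>[C:1](=[O:2])[O:3].[CX4:4][OH]", "Likely"),
    ("bt0004", "amide hydrolysis",
     "[C:1](=[O:2])[NX3:3]>>[C:1](=[O:2])[OH].[NX3:3]", "Neutral"),
    ("bt0005", "aromatic hydroxylation",
     "[cH:1]>>[c:1][OH]", "Neutral"),
    ("bt0006", "N-demethylation",
     "[NX3:1][CH3:2]>>[NX3:1].[CH3:2][OH]", "Unlikely"),
    ("bt0007", "O-demethylation",
     "[#6:3][O:1][CH3:2]>>[#6:3][O:1].[CH3:2][OH]", "Unlikely"),
    ("bt0008", "aromatic nitro reduction",
     "[c:1][N+](=O)[O-]>>[c:1]N", "Very Unlikely"),
]

#: exemplar substrate and expected product sets per rule, hand-validated;
#: regenerated independently by scripts/regen_oracle.py
EXEMPLARS: dict[str, tuple[str, list[tuple[str, ...]]]] = {
    "bt0001": ("CCO", [("CC=O",)]),
    "bt0002": ("CC=O", [("CC(=O)O",)]),
    "bt0003": ("COC(C)=O", [("CC(=O)O", "CO")]),
    "bt0004": ("CC(N)=O", [("CC(=O)O", "N")]),
    "bt0005": ("c1ccccc1", [("Oc1ccccc1",)]),
    "bt0006": ("CNc1ccccc1", [("CO", "Nc1ccccc1")]),
    "bt0007": ("COc1ccccc1", [("CO", "Oc1ccccc1")]),
    "bt0008": ("O=[N+]([O-])c1ccccc1", [("Nc1ccccc1",)]),
}

#: ~20 small molecules guaranteed to trigger rules of the toy library
ROOT_COMPOUNDS: list[tuple[str, str]] = [
    ("CCO", "ethanol"),
    ("CCCO", "propan-1-ol"),
    ("OCc1ccccc1", "benzyl alcohol"),
    ("OCCO", "ethylene glycol"),
    ("CC=O", "acetaldehyde"),
    ("O=Cc1ccccc1", "benzaldehyde"),
    ("COC(C)=O", "methyl acetate"),
    ("CCOC(C)=O", "ethyl acetate"),
    ("COC(=O)c1ccccc1", "methyl benzoate"),
    ("CC(N)=O", "acetamide"),
    ("NC(=O)c1ccccc1", "benzamide"),
    ("CNC(C)=O", "N-methylacetamide"),
    ("COc1ccccc1", "anisole"),
    ("COc1ccc(C)cc1", "4-methylanisole"),
    ("O=[N+]([O-])c1ccccc1", "nitrobenzene"),
    ("Cc1ccc([N+](=O)[O-])cc1", "4-nitrotoluene"),
    ("CN(C)C", "trimethylamine"),
    ("CNc1ccccc1", "N-methylaniline"),
    ("Cc1ccccc1", "toluene"),
    ("CCOC(=O)c1ccc([N+](=O)[O-])cc1", "ethyl 4-nitrobenzoate"),
]


def toy_rule_library() -> list[TransformationRule]:
    """Eight hand-validated biotransformation rules covering all five
    aerobic-likelihood categories."""
    return [
        parse_rule(smirks, name, likelihood, rule_id=rule_id)
        for rule_id, name, smirks, likelihood in _RULE_SPECS
    ]


def explosion_ruleset() -> list[TransformationRule]:
    """Rules that trigger on their own products indefinitely.

    Four substituent additions on any aliphatic C–H; from ethane the
    per-level unique-product counts grow 4, 20, 70, …, so uncapped
    expansion exceeds 50 products by level 3.  Used to exercise the
    product-cap stopping criterion.
    """
    specs = [
        ("x0001", "aliphatic methylation", "[CX4;!H0:1]>>[C:1]C"),
        ("x0002", "aliphatic hydroxylation", "[CX4;!H0:1]>>[C:1]O"),
        ("x0003", "aliphatic chlorination", "[CX4;!H0:1]>>[C:1]Cl"),
        ("x0004", "aliphatic amination", "[CX4;!H0:1]>>[C:1]N"),
    ]
    return [parse_rule(smirks, name, "Neutral", rule_id=rid) for rid, name, smirks in specs]


EXPLOSION_ROOT = "CC"  # ethane


# ---------------------------------------------------------------------------
# Synthetic packages
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a synthetic ground-truth package.

    ``active_subset`` indexes into the toy rule library: only those rules
    generate reactions; the full library is still attached so inactive
    rules yield triggered-but-unobserved negatives during training.
    ``noise_rate`` is the probability that a true active-rule reaction is
    omitted from the package (imperfect curation).
    """

    n_rules: int = 8
    # default active set: alcohol oxidation chain + ester hydrolysis +
    # O-demethylation.  Ground-truth labels are defined by product identity,
    # so two rules that predict identical product sets on a shared substrate
    # (ester hydrolysis and O-demethylation both cleave methyl esters to
    # acid + methanol) must not be split across the active/inactive line.
    active_subset: tuple[int, ...] = (0, 1, 2, 6)
    n_root_compounds: int = 20
    max_chain_length: int = 3
    seed: int = 0
    noise_rate: float = 0.1

    def __post_init__(self) -> None:
        if not all(0 <= i < self.n_rules for i in self.active_subset):
            raise ValidationError("active_subset indices must lie in [0, n_rules)")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValidationError("noise_rate must be in [0, 0.5)")
        if self.n_rules > len(_RULE_SPECS):
            raise ValidationError(f"at most {len(_RULE_SPECS)} toy rules available")
        if self.n_root_compounds > len(ROOT_COMPOUNDS):
            raise ValidationError(f"at most {len(ROOT_COMPOUNDS)} root compounds available")


def synthetic_package(
    spec: SyntheticSpec,
    store: Store,
    name: str = "synthetic",
    owner: str = "fixture-bot",
) -> Package:
    """Deterministically build a ground-truth package from a spec.

    For each root compound, pathways are grown by applying only the active
    rules up to ``max_chain_length`` levels; each candidate reaction is
    dropped with probability ``noise_rate``.  A scenario with synthetic
    conditions is attached, plus per-compound half-lives drawn log-uniformly
    from [1, 100] days.  Same (spec, seed) → identical package content.
    """
    rng = np.random.default_rng(spec.seed)
    rules = toy_rule_library()[: spec.n_rules]
    active = [rules[i] for i in spec.active_subset]

    pkg = store.create_package(
        name=name, owner=owner, visibility="public",
        created_at=datetime(2020, 1, 1),
    )
    pid = pkg.package_id
    for rule in rules:
        store.add_entity(pid, rule)
    scenario_id = store.add_entity(
        pid,
        Scenario(
            description="synthetic aerobic soil study (generated fixture)",
            conditions={"matrix": "soil", "study_type": "synthetic", "redox": "aerobic"},
        ),
    )

    n_reactions = 0
    for smiles, label in ROOT_COMPOUNDS[: spec.n_root_compounds]:
        root = canonicalize(smiles, display_name=label)
        pathway = Pathway(root=root, provenance="manual", status="completed")
        store.add_entity(pid, pathway)
        store.add_entity(pid, root)
        frontier = [root]
        seen = {root.smiles_canonical}
        for depth in range(1, spec.max_chain_length + 1):
            next_frontier = []
            for compound in frontier:
                for rule in active:
                    for pset in apply_rule(rule, compound):
                        if rng.random() < spec.noise_rate:
                            continue  # curation gap: reaction omitted
                        educt_id = store.add_entity(pid, compound)
                        product_ids = [store.add_entity(pid, c) for c in pset.products]
                        store.add_entity(
                            pid,
                            Reaction(
                                educts=[educt_id],
                                products=product_ids,
                                rule_link=rule.rule_id,
                                scenario_links=[scenario_id],
                            ),
                        )
                        n_reactions += 1
                        pathway.edges.append(
                            PathwayEdge(
                                educt=compound.smiles_canonical,
                                products=[c.smiles_canonical for c in pset.products],
                                rule_id=rule.rule_id,
                            )
                        )
                        for product in pset.products:
                            if product.smiles_canonical not in seen:
                                seen.add(product.smiles_canonical)
                                pathway.nodes[product.smiles_canonical] = product
                                pathway.node_depth[product.smiles_canonical] = depth
                                next_frontier.append(product)
            frontier = next_frontier
        half_life = float(10 ** rng.uniform(0, 2))
        store.add_entity(
            pid,
            HalfLifeAnnotation(
                compound=pkg.smiles_index[root.smiles_canonical],
                pathway=pathway.pathway_id,
                scenario=scenario_id,
                half_life_value=round(half_life, 3),
                half_life_units="days",
            ),
        )

    if n_reactions == 0:
        raise GenerationError(
            "active rule subset produced no reactions on the generated roots; "
            f"active={list(spec.active_subset)}, roots={spec.n_root_compounds}"
        )
    return pkg
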