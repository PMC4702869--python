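"""Entity graph: packages of compounds, rules, reactions, pathways, scenarios.

A *package* is the unit of sharing, review and machine-learning ground
truth.  Every entity lives in exactly one package and is addressed by a
URI-like identifier ``pkg/<uuid>/<entitytype>/<uuid>``.  The store is an
in-process document store persisted as JSON — no server, no RDF — but the
identifier scheme keeps link semantics so the documents remain servable.

Curation semantics: packages start ``unreviewed``; after the owner submits
and a reviewer approves, the package is ``reviewed`` and all mutation is
restricted to reviewers.  Everything created by the anonymous user is
purged after a retention period (default 30 days); registered users' data
are never purged automatically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .chem import Compound, TransformationRule, canonicalize, parse_rule
from .errors import IntegrityError, PermissionDenied, ValidationError

logger = logging.getLogger(__name__)

ANONYMOUS = "anonymous"
HALF_LIFE_UNITS = ("hours", "days")

_NS = uuid.uuid5(uuid.NAMESPACE_URL, "biotrans-store")


@dataclass
class Reaction:
    """An educt→products transformation, optionally linked to the rule that
    predicted it and to the scenarios under which it was observed."""

    educts: list[str]
    products: list[str]
    rule_link: str | None = None
    scenario_links: list[str] = field(default_factory=list)
    external_refs: dict[str, str] = field(default_factory=dict)
    reaction_id: str | None = None


@dataclass
class Scenario:
    """Experimental/environmental conditions annotation (free key-value)."""

    description: str
    conditions: dict[str, str] = field(default_factory=dict)
    scenario_id: str | None = None


@dataclass
class HalfLifeAnnotation:
    """A biotransformation half-life for a compound in a pathway under a
    specific scenario."""

    compound: str
    pathway: str
    scenario: str
    half_life_value: float
    half_life_units: str = "days"
    annotation_id: str | None = None

    def __post_init__(self) -> None:
        if self.half_life_value <= 0:
            raise ValidationError("half_life_value must be positive")
        if self.half_life_units not in HALF_LIFE_UNITS:
            raise ValidationError(
                f"half_life_units must be one of {HALF_LIFE_UNITS}"
            )


@dataclass
class Package:
    package_id: str
    name: str
    owner: str
    visibility: str
    created_at: datetime
    review_status: str = "unreviewed"
    submitted: bool = False
    compounds: dict[str, Compound] = field(default_factory=dict)
    rules: dict[str, TransformationRule] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways: dict[str, object] = field(default_factory=dict)
    scenarios: dict[str, Scenario] = field(default_factory=dict)
    half_lives: dict[str, HalfLifeAnnotation] = field(default_factory=dict)
    # canonical SMILES -> compound id, for dedup on insert
    smiles_index: dict[str, str] = field(default_factory=dict)

    def compound_by_smiles(self, canonical: str) -> Compound | None:
        cid = self.smiles_index.get(canonical)
        return self.compounds[cid] if cid else None


class Store:
    """In-process entity store.

    Identifiers are minted deterministically from a per-store counter, so an
    identical sequence of operations on a fresh store yields byte-identical
    exports — required for reproducible fixtures and predictions.
    """

    def __init__(self) -> None:
        self.packages: dict[str, Package] = {}
        self.reviewers: set[str] = set()
        self._counter = 0

    # -- identifier minting -------------------------------------------------
    def _mint(self, prefix: str) -> str:
        while True:
            self._counter += 1
            ident = f"{prefix}/{uuid.uuid5(_NS, str(self._counter))}"
            if not self._exists(ident):
                return ident

    def _exists(self, ident: str) -> bool:
        if ident in self.packages:
            return True
        for pkg in self.packages.values():
            for coll in (pkg.compounds, pkg.rules, pkg.reactions,
                         pkg.pathways, pkg.scenarios, pkg.half_lives):
                if ident in coll:
                    return True
        return False

    # -- package lifecycle --------------------------------------------------
    def create_package(
        self,
        name: str,
        owner: str = ANONYMOUS,
        visibility: str = "public",
        created_at: datetime | None = None,
    ) -> Package:
        """Create an empty, unreviewed package and register it.

        ``created_at`` is caller-supplied (injectable clock) so retention is
        deterministic in tests; it defaults to the current UTC time.
        """
        if not name:
            raise ValidationError("package name must be non-empty")
        if visibility not in ("public", "private"):
            raise ValidationError("visibility must be 'public' or 'private'")
        package_id = self._mint("pkg")
        pkg = Package(
            package_id=package_id,
            name=name,
            owner=owner,
            visibility=visibility,
            created_at=created_at or datetime.utcnow(),
        )
        self.packages[package_id] = pkg
        return pkg

    def get_package(self, package_id: str) -> Package:
        try:
            return self.packages[package_id]
        except KeyError:
            raise IntegrityError(f"unknown package: {package_id}") from None

    def _check_mutable(self, pkg: Package, actor: str) -> None:
        if pkg.review_status == "reviewed" and actor not in self.reviewers:
            raise PermissionDenied(
                f"package {pkg.name!r} is reviewed; only reviewers may modify it"
            )

    # -- entity insertion ---------------------------------------------------
    def add_entity(self, package_id: str, entity, actor: str | None = None) -> str:
        """Insert an entity into a package and return its identifier.

        Compounds are deduplicated by canonical SMILES (re-inserting is a
        no-op returning the existing id).  References carried by the entity
        (rule links, scenario links, compound ids) must already resolve
        within the package, otherwise :class:`IntegrityError` is raised.
        Mutation of a reviewed package requires a reviewer ``actor``.
        """
        pkg = self.get_package(package_id)
        self._check_mutable(pkg, actor if actor is not None else pkg.owner)

        if isinstance(entity, Compound):
            existing = pkg.smiles_index.get(entity.smiles_canonical)
            if existing:
                return existing
            cid = self._mint(f"{package_id}/compound")
            pkg.compounds[cid] = entity
            pkg.smiles_index[entity.smiles_canonical] = cid
            return cid

        if isinstance(entity, TransformationRule):
            if entity.rule_id in pkg.rules:
                return entity.rule_id
            if entity.composite_members:
                missing = [m for m in entity.composite_members if m not in pkg.rules]
                if missing:
                    raise IntegrityError(
                        f"composite rule {entity.rule_id} references absent members: {missing}"
                    )
            pkg.rules[entity.rule_id] = entity
            return entity.rule_id

        if isinstance(entity, Reaction):
            if not entity.educts or not entity.products:
                raise ValidationError("reaction educts and products must be non-empty")
            for cid in [*entity.educts, *entity.products]:
                if cid not in pkg.compounds:
                    raise IntegrityError(f"reaction references absent compound: {cid}")
            if entity.rule_link is not None and entity.rule_link not in pkg.rules:
                raise IntegrityError(f"reaction references absent rule: {entity.rule_link}")
            for sid in entity.scenario_links:
                if sid not in pkg.scenarios:
                    raise IntegrityError(f"reaction references absent scenario: {sid}")
            if entity.reaction_id is None:
                entity.reaction_id = self._mint(f"{package_id}/reaction")
            pkg.reactions[entity.reaction_id] = entity
            return entity.reaction_id

        if isinstance(entity, Scenario):
            if entity.scenario_id is None:
                entity.scenario_id = self._mint(f"{package_id}/scenario")
            pkg.scenarios[entity.scenario_id] = entity
            return entity.scenario_id

        if isinstance(entity, HalfLifeAnnotation):
            if entity.compound not in pkg.compounds:
                raise IntegrityError(f"half-life references absent compound: {entity.compound}")
            if entity.pathway not in pkg.pathways:
                raise IntegrityError(f"half-life references absent pathway: {entity.pathway}")
            if entity.scenario not in pkg.scenarios:
                raise IntegrityError(f"half-life references absent scenario: {entity.scenario}")
            if entity.annotation_id is None:
                entity.annotation_id = self._mint(f"{package_id}/halflife")
            pkg.half_lives[entity.annotation_id] = entity
            return entity.annotation_id

        # pathways are duck-typed to avoid a circular import with the engine
        if hasattr(entity, "nodes") and hasattr(entity, "edges"):
            if entity.pathway_id is None:
                entity.pathway_id = self._mint(f"{package_id}/pathway")
            pkg.pathways[entity.pathway_id] = entity
            return entity.pathway_id

        raise ValidationError(f"unsupported entity type: {type(entity).__name__}")

    # -- review workflow ----------------------------------------------------
    def submit_for_review(self, package_id: str, actor: str) -> Package:
        """Owner submits the package for review (idempotent)."""
        pkg = self.get_package(package_id)
        if actor != pkg.owner and actor not in self.reviewers:
            raise PermissionDenied("only the owner may submit a package for review")
        pkg.submitted = True
        return pkg

    def review(self, package_id: str, actor: str, approve: bool) -> Package:
        """Reviewer approves (locks) or rejects the package.

        Re-reviewing an already-reviewed package is a no-op.
        """
        pkg = self.get_package(package_id)
        if actor not in self.reviewers:
            raise PermissionDenied(f"{actor!r} is not a reviewer")
        if approve and pkg.review_status != "reviewed":
            pkg.review_status = "reviewed"
        return pkg

    # -- retention ----------------------------------------------------------
    def purge_expired(self, now: datetime, retention_days: int = 30) -> list[str]:
        """Delete anonymous-owned packages older than the retention window.

        Returns the identifiers of everything deleted (packages and their
        contained entities).  Registered users' data are never touched.
        Idempotent: a second call at the same ``now`` deletes nothing.
        """
        if retention_days <= 0:
            raise ValidationError("retention_days must be positive")
        deleted: list[str] = []
        cutoff = timedelta(days=retention_days)
        for pid in list(self.packages):
            pkg = self.packages[pid]
            if pkg.owner != ANONYMOUS:
                continue
            if now - pkg.created_at > cutoff:
                deleted.append(pid)
                for coll in (pkg.compounds, pkg.rules, pkg.reactions,
                             pkg.pathways, pkg.scenarios, pkg.half_lives):
                    deleted.extend(coll.keys())
                del self.packages[pid]
        return deleted


# ---------------------------------------------------------------------------
# JSON export / import
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def export_package(pkg: Package) -> dict:
    """Serialize a package to a plain JSON-able document.

    The document is deterministic: collections are emitted in sorted-id
    order and ``dumps_canonical`` gives byte-identical output for equal
    packages, so export→import→export round-trips exactly.
    """
    from .engine import pathway_to_dict  # deferred: engine imports this module

    return {
        "schema_version": SCHEMA_VERSION,
        "package": {
            "package_id": pkg.package_id,
            "name": pkg.name,
            "owner": pkg.owner,
            "visibility": pkg.visibility,
            "review_status": pkg.review_status,
            "submitted": pkg.submitted,
            "created_at": pkg.created_at.isoformat(),
        },
        "compounds": [
            {
                "id": cid,
                "smiles": c.smiles_canonical,
                "smiles_input": c.smiles_input,
                "display_name": c.display_name,
            }
            for cid, c in sorted(pkg.compounds.items())
        ],
        "rules": [
            {
                "rule_id": r.rule_id,
                "name": r.name,
                "smirks": r.smirks,
                "likelihood": r.likelihood.value,
                "composite_members": r.composite_members,
            }
            for _, r in sorted(pkg.rules.items())
        ],
        "reactions": [
            {
                "reaction_id": rid,
                "educts": rx.educts,
                "products": rx.products,
                "rule_link": rx.rule_link,
                "scenario_links": rx.scenario_links,
                "external_refs": rx.external_refs,
            }
            for rid, rx in sorted(pkg.reactions.items())
        ],
        "pathways": [
            pathway_to_dict(pw) for _, pw in sorted(pkg.pathways.items())
        ],
        "scenarios": [
            {
                "scenario_id": sid,
                "description": s.description,
                "conditions": s.conditions,
            }
            for sid, s in sorted(pkg.scenarios.items())
        ],
        "half_lives": [
            {
                "annotation_id": aid,
                "compound": h.compound,
                "pathway": h.pathway,
                "scenario": h.scenario,
                "half_life_value": h.half_life_value,
                "half_life_units": h.half_life_units,
            }
            for aid, h in sorted(pkg.half_lives.items())
        ],
    }


def dumps_canonical(doc: dict) -> str:
    """Canonical JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(doc, sort_keys=True, indent=1, ensure_ascii=True)


def package_content_hash(pkg: Package) -> str:
    """SHA-256 over the canonical JSON export."""
    return hashlib.sha256(dumps_canonical(export_package(pkg)).encode()).hexdigest()


def import_package(store: Store, doc: dict) -> Package:
    """Validate a package document against the schema and load it.

    Validation errors report the JSON path of the offending field.
    Identifiers in the document are preserved verbatim.
    """
    from .engine import pathway_from_dict
    from .schema import validate_package_doc

    model = validate_package_doc(doc)

    meta = model.package
    if meta.package_id in store.packages:
        raise IntegrityError(f"package already present: {meta.package_id}")
    pkg = Package(
        package_id=meta.package_id,
        name=meta.name,
        owner=meta.owner,
        visibility=meta.visibility,
        created_at=datetime.fromisoformat(meta.created_at),
        review_status=meta.review_status,
        submitted=meta.submitted,
    )
    for c in model.compounds:
        comp = canonicalize(c.smiles_input, display_name=c.display_name)
        if comp.smiles_canonical != c.smiles:
            # keep the recorded canonical form as authoritative key
            comp = Compound(c.smiles_input, c.smiles, c.display_name)
        pkg.compounds[c.id] = comp
        pkg.smiles_index[comp.smiles_canonical] = c.id
    for r in model.rules:
        pkg.rules[r.rule_id] = parse_rule(
            r.smirks, r.name, r.likelihood, rule_id=r.rule_id,
            composite_members=r.composite_members,
        )
    for rx in model.reactions:
        pkg.reactions[rx.reaction_id] = Reaction(
            educts=list(rx.educts),
            products=list(rx.products),
            rule_link=rx.rule_link,
            scenario_links=list(rx.scenario_links),
            external_refs=dict(rx.external_refs),
            reaction_id=rx.reaction_id,
        )
    for s in model.scenarios:
        pkg.scenarios[s.scenario_id] = Scenario(
            description=s.description, conditions=dict(s.conditions),
            scenario_id=s.scenario_id,
        )
    for pw in model.pathways:
        pathway = pathway_from_dict(pw.model_dump())
        pkg.pathways[pathway.pathway_id] = pathway
    for h in model.half_lives:
        pkg.half_lives[h.annotation_id] = HalfLifeAnnotation(
            compound=h.compound, pathway=h.pathway, scenario=h.scenario,
            half_life_value=h.half_life_value, half_life_units=h.half_life_units,
            annotation_id=h.annotation_id,
        )
    store.packages[pkg.package_id] = pkg
    return pkg
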