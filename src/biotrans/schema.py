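"""Pydantic models defining the package JSON document schema.

These models exist purely for import-side validation; the in-memory domain
objects live in :mod:`biotrans.datamodel`.  Validation failures are
reported with the JSON path of the offending field.
"""

from __future__ import annotations

import pydantic
from pydantic import BaseModel, Field

from .errors import ValidationError


class PackageMeta(BaseModel):
    package_id: str
    name: str = Field(min_length=1)
    owner: str
    visibility: str = Field(pattern="^(public|private)$")
    review_status: str = Field(pattern="^(reviewed|unreviewed)$")
    submitted: bool = False
    created_at: str


class CompoundDoc(BaseModel):
    id: str
    smiles: str = Field(min_length=1)
    smiles_input: str = Field(min_length=1)
    display_name: str | None = None


class RuleDoc(BaseModel):
    rule_id: str
    name: str
    smirks: str = Field(min_length=1)
    likelihood: str
    composite_members: list[str] | None = None


class ReactionDoc(BaseModel):
    reaction_id: str
    educts: list[str] = Field(min_length=1)
    products: list[str] = Field(min_length=1)
    rule_link: str | None = None
    scenario_links: list[str] = Field(default_factory=list)
    external_refs: dict[str, str] = Field(default_factory=dict)


class PathwayNodeDoc(BaseModel):
    smiles: str
    display_name: str | None = None
    depth: int = 0


class PathwayEdgeDoc(BaseModel):
    educt: str
    products: list[str] = Field(min_length=1)
    rule_id: str | None = None
    score: float | None = None
    reaction_id: str | None = None


class PathwayDoc(BaseModel):
    pathway_id: str
    root: str
    nodes: list[PathwayNodeDoc]
    edges: list[PathwayEdgeDoc]
    status: str = Field(pattern="^(in_progress|completed)$")
    provenance: str = Field(pattern="^(predicted|manual)$")
    annotations: dict[str, object] = Field(default_factory=dict)


class ScenarioDoc(BaseModel):
    scenario_id: str
    description: str
    conditions: dict[str, str] = Field(default_factory=dict)


class HalfLifeDoc(BaseModel):
    annotation_id: str
    compound: str
    pathway: str
    scenario: str
    half_life_value: float = Field(gt=0)
    half_life_units: str = Field(pattern="^(hours|days)$")


class PackageDoc(BaseModel):
    schema_version: int
    package: PackageMeta
    compounds: list[CompoundDoc] = Field(default_factory=list)
    rules: list[RuleDoc] = Field(default_factory=list)
    reactions: list[ReactionDoc] = Field(default_factory=list)
    pathways: list[PathwayDoc] = Field(default_factory=list)
    scenarios: list[ScenarioDoc] = Field(default_factory=list)
    half_lives: list[HalfLifeDoc] = Field(default_factory=list)


def validate_package_doc(doc: dict) -> PackageDoc:
    try:
        return PackageDoc.model_validate(doc)
    except pydantic.ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = "$." + ".".join(str(p) for p in err["loc"])
            lines.append(f"{path}: {err['msg']}")
        raise ValidationError(
            "package document failed schema validation:\n" + "\n".join(lines)
        ) from exc
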