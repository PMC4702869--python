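"""Structure and rule primitives.

Compounds are keyed by canonical SMILES; biotransformation rules are SMIRKS
transforms whose left-hand side is a functional-group pattern and whose
right-hand side describes the transformation via atom maps.  Applying a rule
to a compound yields zero or more *product sets* — one transformation event
may produce several co-products (e.g. hydrolyses).

RDKit provides the underlying SMILES/SMARTS/SMIRKS machinery; this module
adds the conventions the rest of the package relies on:

* multi-fragment canonical SMILES are fragment-wise canonicalized and
  sorted-joined, so the dot-separated order never matters for identity;
* product sets are deduplicated across symmetric matches by their sorted
  canonical product SMILES;
* products that fail chemical sanitization (impossible valence after the
  transform) are dropped with a warning rather than aborting prediction.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field
from functools import total_ordering

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import SmilesParseError, SmirksParseError, ValidationError

logger = logging.getLogger(__name__)

# RDKit is chatty on stderr about sanitization failures we handle ourselves.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


@total_ordering
class Likelihood(enum.Enum):
    """Expert-assigned aerobic likelihood of a transformation rule.

    Exactly five ordered categories; comparison follows
    Very Likely > Likely > Neutral > Unlikely > Very Unlikely.
    """

    VERY_LIKELY = "Very Likely"
    LIKELY = "Likely"
    NEUTRAL = "Neutral"
    UNLIKELY = "Unlikely"
    VERY_UNLIKELY = "Very Unlikely"

    @property
    def rank(self) -> int:
        """0 for Very Unlikely up to 4 for Very Likely."""
        order = [
            Likelihood.VERY_UNLIKELY,
            Likelihood.UNLIKELY,
            Likelihood.NEUTRAL,
            Likelihood.LIKELY,
            Likelihood.VERY_LIKELY,
        ]
        return order.index(self)

    def __lt__(self, other: "Likelihood") -> bool:
        if not isinstance(other, Likelihood):
            return NotImplemented
        return self.rank < other.rank

    @classmethod
    def from_string(cls, value: "str | Likelihood") -> "Likelihood":
        """Parse a category label; anything outside the five is rejected."""
        if isinstance(value, cls):
            return value
        for member in cls:
            if member.value == value:
                return member
        accepted = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"unknown likelihood category {value!r}; accepted values: {accepted}"
        )


@dataclass(frozen=True)
class Compound:
    """An immutable structure record, identified by canonical SMILES."""

    smiles_input: str
    smiles_canonical: str
    display_name: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Compound):
            return NotImplemented
        return self.smiles_canonical == other.smiles_canonical

    def __hash__(self) -> int:
        return hash(self.smiles_canonical)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def _canonical_fragments(mol: Chem.Mol) -> list[str]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return sorted(Chem.MolToSmiles(f) for f in frags)


def canonicalize(smiles: str, display_name: str | None = None) -> Compound:
    """Parse a SMILES string and return a canonicalized :class:`Compound`.

    Multi-fragment (dot-disconnected) inputs are accepted; each fragment is
    canonicalized independently and the fragments joined in sorted order, so
    the canonical form is independent of fragment order in the input.

    Raises
    ------
    SmilesParseError
        If the string is empty or does not parse.
    """
    mol = _mol_from_smiles(smiles)
    canonical = ".".join(_canonical_fragments(mol))
    return Compound(smiles_input=smiles, smiles_canonical=canonical, display_name=display_name)


_slug_re = re.compile(r"[^a-z0-9]+")


def _slugify(name: str) -> str:
    return _slug_re.sub("-", name.lower()).strip("-") or "rule"


@dataclass
class TransformationRule:
    """A named SMIRKS transform with an aerobic-likelihood category.

    ``composite_members`` allows representing a rule defined as a set of
    alternative sub-rules; the engine treats such a rule as opaque and only
    records the ids.
    """

    rule_id: str
    name: str
    smirks: str
    likelihood: Likelihood
    composite_members: list[str] | None = None
    _rxn: AllChem.ChemicalReaction = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.likelihood = Likelihood.from_string(self.likelihood)
        if self._rxn is None:
            self._rxn = _reaction_from_smirks(self.smirks)

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        return self._rxn

    @property
    def reactant_template(self) -> Chem.Mol:
        return self._rxn.GetReactantTemplate(0)


def _reaction_from_smirks(smirks: str) -> AllChem.ChemicalReaction:
    if ">>" not in smirks:
        raise SmirksParseError(smirks, "missing '>>' separator")
    try:
        rxn = AllChem.ReactionFromSmarts(smirks)
    except Exception as exc:  # RDKit raises bare ValueError subclasses
        raise SmirksParseError(smirks, str(exc)) from exc
    if rxn is None:
        raise SmirksParseError(smirks)
    if rxn.GetNumReactantTemplates() < 1:
        raise SmirksParseError(smirks, "no reactant template")
    if rxn.GetNumProductTemplates() < 1:
        raise SmirksParseError(smirks, "no product template")
    rxn.Initialize()
    return rxn


def parse_rule(
    smirks: str,
    name: str,
    likelihood: "str | Likelihood",
    rule_id: str | None = None,
    composite_members: list[str] | None = None,
) -> TransformationRule:
    """Build an executable :class:`TransformationRule` from a SMIRKS string.

    The SMIRKS round-trips: the stored string is kept verbatim, so exporting
    and re-parsing yields an equivalent transform.

    Raises
    ------
    SmirksParseError
        If the SMIRKS does not parse or lacks reactant/product templates.
    ValidationError
        If the likelihood is not one of the five categories.
    """
    category = Likelihood.from_string(likelihood)
    if rule_id is None:
        rule_id = _slugify(name)
    return TransformationRule(
        rule_id=rule_id,
        name=name,
        smirks=smirks,
        likelihood=category,
        composite_members=composite_members,
    )


@dataclass(frozen=True)
class ProductSet:
    """Products of one transformation event (one structural match).

    ``key`` — the lexicographically sorted tuple of canonical product
    SMILES — is the deduplication identity across symmetric matches.
    """

    products: tuple[Compound, ...]
    source_rule: str
    match_index: int

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(c.smiles_canonical for c in self.products))


def triggers(rule: TransformationRule, compound: Compound) -> bool:
    """True iff the rule's left-hand-side pattern matches the compound."""
    mol = _mol_from_smiles(compound.smiles_canonical)
    if rule.rxn.GetNumReactantTemplates() != 1:
        logger.warning(
            "rule %s has %d reactant templates; only single-educt rules trigger",
            rule.rule_id,
            rule.rxn.GetNumReactantTemplates(),
        )
        return False
    return mol.HasSubstructMatch(rule.reactant_template)


def load_rules(path) -> list[TransformationRule]:
    """Read rules from a JSON-lines file: one object per line with fields
    {rule_id, name, smirks, likelihood[, composite_members]}."""
    rules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                doc = json.loads(line)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: not valid JSON ({exc})") from exc
            rules.append(
                parse_rule(
                    doc["smirks"], doc.get("name", doc["rule_id"]), doc["likelihood"],
                    rule_id=doc["rule_id"],
                    composite_members=doc.get("composite_members"),
                )
            )
    return rules


def dump_rules(rules: list[TransformationRule], path) -> None:
    """Write rules as JSON lines (round-trips with :func:`load_rules`)."""
    with open(path, "w") as fh:
        for rule in rules:
            doc = {
                "rule_id": rule.rule_id,
                "name": rule.name,
                "smirks": rule.smirks,
                "likelihood": rule.likelihood.value,
            }
            if rule.composite_members:
                doc["composite_members"] = rule.composite_members
            fh.write(json.dumps(doc, sort_keys=True) + "\n")


def apply_rule(rule: TransformationRule, compound: Compound) -> list[ProductSet]:
    """Apply a rule to a compound, returning one ProductSet per distinct match.

    Every product molecule is sanitized (valence-checked) and canonicalized;
    a match whose products fail sanitization is skipped with a warning.
    Multi-fragment products are split into individual compounds.  Product
    sets identical after canonicalization (symmetric matches) are merged.
    Returns an empty list when the rule does not trigger.
    """
    mol = _mol_from_smiles(compound.smiles_canonical)
    if rule.rxn.GetNumReactantTemplates() != 1:
        return []
    results: list[ProductSet] = []
    seen: set[tuple[str, ...]] = set()
    for match_index, product_mols in enumerate(rule.rxn.RunReactants((mol,))):
        compounds: list[Compound] = []
        try:
            for pmol in product_mols:
                Chem.SanitizeMol(pmol)
                for frag_smiles in _canonical_fragments(pmol):
                    compounds.append(canonicalize(frag_smiles))
        except Exception as exc:
            logger.warning(
                "rule %s on %s: match %d dropped (%s)",
                rule.rule_id,
                compound.smiles_canonical,
                match_index,
                exc,
            )
            continue
        if not compounds:
            continue
        pset = ProductSet(
            products=tuple(compounds), source_rule=rule.rule_id, match_index=match_index
        )
        if pset.key in seen:
            continue
        seen.add(pset.key)
        results.append(pset)
    return results
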