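#!/usr/bin/env python
"""Regenerate the fixture exemplar table independently and diff it.

Recomputes, via direct RDKit transform application (no package wrapper
logic), the expected product sets of every toy rule on its documented
exemplar substrate, and compares them with the frozen ``EXEMPLARS`` table
in :mod:`biotrans.fixtures`.  Exits non-zero on any difference so CI
catches drift between the table and the chemistry.
"""

import sys

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from biotrans.fixtures import EXEMPLARS, toy_rule_library

RDLogger.DisableLog("rdApp.*")


def direct_apply(smirks: str, smiles: str) -> list[tuple[str, ...]]:
    rxn = AllChem.ReactionFromSmarts(smirks)
    mol = Chem.MolFromSmiles(smiles)
    out = set()
    for product_mols in rxn.RunReactants((mol,)):
        frags, ok = [], True
        for pmol in product_mols:
            try:
                Chem.SanitizeMol(pmol)
            except Exception:
                ok = False
                break
            frags.extend(
                Chem.MolToSmiles(f)
                for f in Chem.GetMolFrags(pmol, asMols=True, sanitizeFrags=False)
            )
        if ok and frags:
            out.add(tuple(sorted(frags)))
    return sorted(out)


def main() -> int:
    failures = 0
    for rule in toy_rule_library():
        substrate, expected = EXEMPLARS[rule.rule_id]
        recomputed = direct_apply(rule.smirks, substrate)
        frozen = sorted(expected)
        status = "ok" if recomputed[: len(frozen)] == frozen else "MISMATCH"
        if status != "ok":
            failures += 1
        print(f"{rule.rule_id} {substrate:>24} {status}")
        if status != "ok":
            print(f"  frozen:     {frozen}")
            print(f"  recomputed: {recomputed}")
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
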