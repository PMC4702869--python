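import pytest
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from biotrans import Store, fixtures

RDLogger.DisableLog("rdApp.*")


def _independent_apply(smirks: str, smiles: str) -> set[tuple[str, ...]]:
    """Reference transform application, independent of the package wrapper.

    Drives RDKit directly — no fragment sorting, ProductSet machinery or
    warning/drop logic — and returns product sets as sorted tuples of
    canonical fragment SMILES.  Used as the oracle against which
    ``apply_rule`` is compared.
    """
    rxn = AllChem.ReactionFromSmarts(smirks)
    mol = Chem.MolFromSmiles(smiles)
    out: set[tuple[str, ...]] = set()
    for product_mols in rxn.RunReactants((mol,)):
        frags: list[str] = []
        ok = True
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
    return out


@pytest.fixture(scope="session")
def oracle_apply():
    return _independent_apply


@pytest.fixture(scope="session")
def toy_library():
    return fixtures.toy_rule_library()


@pytest.fixture(scope="session")
def toy_rules_by_id(toy_library):
    return {r.rule_id: r for r in toy_library}


@pytest.fixture()
def store():
    return Store()


@pytest.fixture(scope="session")
def synthetic_pkg():
    """One shared synthetic ground-truth package (seed 1, defaults)."""
    store = Store()
    return fixtures.synthetic_package(fixtures.SyntheticSpec(seed=1), store)
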