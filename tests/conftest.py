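import pytest

from magsolex.fixtures import example_molecule


@pytest.fixture(scope="session")
def catalog():
    """Every catalog molecule, built once per session."""
    from magsolex.fixtures import catalog_names

    return {name: example_molecule(name) for name in catalog_names()}


@pytest.fixture(scope="session")
def dmen(catalog):
    return catalog["dmen"]


def rdkit_canonical(smiles: str) -> str | None:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None
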