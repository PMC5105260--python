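import pytest
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from cdplib.chemotypes import ChemotypeTable
from cdplib.io import CompoundSet, MoleculeRecord


def record(smiles: str, ident: str = "x") -> MoleculeRecord:
    """Build a curated-style record straight from a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return MoleculeRecord(
        id=ident,
        smiles_raw=smiles,
        smiles_canonical=Chem.MolToSmiles(mol),
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
        n_rings=rdMolDescriptors.CalcNumRings(mol),
    )


def compound_set(smiles_list, name="test"):
    return CompoundSet(name=name,
                       records=[record(s, f"m{i}") for i, s in enumerate(smiles_list, 1)])


def table(counts, name="test"):
    """Chemotype table with synthetic keys k001, k002, ..."""
    return ChemotypeTable(set_name=name,
                          counts={f"k{i:03d}": c for i, c in enumerate(counts, 1)})


@pytest.fixture
def smi_file(tmp_path):
    def _write(lines, fname="lib.smi"):
        path = tmp_path / fname
        path.write_text("\n".join(lines) + "\n")
        return str(path)
    return _write
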