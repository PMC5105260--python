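"""Chemotype extraction and per-library chemotype tables.

A *chemotype* is the core cyclic system of a molecule: every ring plus the
linkers connecting rings, with all substituent atoms pruned.  It is obtained
by iteratively deleting terminal (degree-1) heavy atoms until none remain;
atom and bond types are retained, so benzene and pyridine are distinct
chemotypes.  Ring-free molecules collapse into one shared sentinel
chemotype, ``ACYCLIC`` — a whole class of molecules counts as a single
chemotype, which is exactly how libraries rich in acyclic compounds
(food additives, small carcinogens) end up scoring low scaffold diversity.

By default an atom double-bonded to a ring but outside it (a carbonyl
oxygen, for example) is pruned like any other terminal atom; pass
``keep_exocyclic=True`` to retain such atoms, since conventions differ
between toolkits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from rdkit import Chem
from rdkit.Chem import RWMol

from .io import CompoundSet, MoleculeRecord

ACYCLIC = "ACYCLIC"

__all__ = ["ACYCLIC", "Chemotype", "ChemotypeTable", "extract_chemotype",
           "tabulate", "cyclic_subset"]


@dataclass(frozen=True)
class Chemotype:
    """A scaffold key: canonical framework SMILES or the ``ACYCLIC`` sentinel."""

    key: str

    @property
    def is_acyclic(self) -> bool:
        return self.key == ACYCLIC


@dataclass
class ChemotypeTable:
    """Chemotype population counts for one library.

    Attributes
    ----------
    set_name : name of the library.
    counts : mapping chemotype key -> number of compounds carrying it.
    """

    set_name: str
    counts: dict[str, int]

    @property
    def N(self) -> int:
        """Number of distinct chemotypes."""
        return len(self.counts)

    @property
    def M(self) -> int:
        """Total number of compounds."""
        return sum(self.counts.values())

    @property
    def N_sing(self) -> int:
        """Number of singletons (chemotypes with exactly one compound)."""
        return sum(1 for c in self.counts.values() if c == 1)

    def sorted_counts(self) -> list[tuple[str, int]]:
        """Counts sorted by descending population, ties by ascending key."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def validate(self) -> None:
        if not self.counts:
            raise ValueError(f"chemotype table for {self.set_name!r} is empty")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("chemotype counts must be >= 1")


def _framework_mol(mol: Chem.Mol, keep_exocyclic: bool) -> Chem.Mol:
    rw = RWMol(mol)
    # Kekulize first: pruning a substituent off an aromatic ring (or an
    # exocyclic =O off a 2-pyridone-like ring) must not be blocked by
    # aromatic-perception bookkeeping; aromaticity is re-perceived at the end.
    Chem.Kekulize(rw, clearAromaticFlags=True)
    while True:
        terminal = []
        for atom in rw.GetAtoms():
            if atom.GetDegree() != 1:
                continue
            bond = atom.GetBonds()[0]
            if keep_exocyclic and bond.GetBondType() != Chem.BondType.SINGLE:
                continue
            terminal.append(atom.GetIdx())
        if not terminal:
            break
        for idx in sorted(terminal, reverse=True):
            rw.RemoveAtom(idx)
    out = rw.GetMol()
    for atom in out.GetAtoms():
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    Chem.SanitizeMol(out)
    return out


def extract_chemotype(record: MoleculeRecord | str, keep_exocyclic: bool = False) -> Chemotype:
    """Derive the chemotype of one curated molecule.

    Accepts a :class:`~cdplib.io.MoleculeRecord` or a SMILES string.
    Returns the ``ACYCLIC`` sentinel for ring-free molecules, otherwise the
    canonical SMILES of the framework (rings + linkers, substituents pruned).
    """
    if isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {record!r}")
    else:
        mol = record.mol()
    if mol.GetRingInfo().NumRings() == 0:
        return Chemotype(ACYCLIC)
    fw = _framework_mol(mol, keep_exocyclic=keep_exocyclic)
    return Chemotype(Chem.MolToSmiles(fw))


def tabulate(cset: CompoundSet, keep_exocyclic: bool = False) -> ChemotypeTable:
    """Aggregate chemotype counts over every record of a library."""
    if len(cset) == 0:
        raise ValueError(f"cannot tabulate empty set {cset.name!r}")
    counter: Counter[str] = Counter(
        extract_chemotype(rec, keep_exocyclic=keep_exocyclic).key for rec in cset
    )
    table = ChemotypeTable(set_name=cset.name, counts=dict(counter))
    table.validate()
    return table


def cyclic_subset(cset: CompoundSet, name: Optional[str] = None) -> CompoundSet:
    """Drop all ring-free molecules, mirroring a 'cyclic systems only' subset."""
    kept = [rec for rec in cset if rec.n_rings > 0]
    return CompoundSet(name=name or f"{cset.name} subset", records=kept,
                       n_skipped=cset.n_skipped, n_rejected=cset.n_rejected)


def write_chemotypes_tsv(tables: list[ChemotypeTable], path: str) -> None:
    """Long-format dump: set_name, chemotype_key, count; descending count."""
    with open(path, "w") as fh:
        fh.write("set_name\tchemotype_key\tcount\n")
        for table in tables:
            for key, count in table.sorted_counts():
                fh.write(f"{table.set_name}\t{key}\t{count}\n")
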