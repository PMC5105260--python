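"""Reading, curating and deduplicating compound libraries.

A library enters the pipeline as a SMILES file (one record per line,
optionally ``SMILES<TAB>ID``) or an SDF.  Every record is curated with a
deterministic standardization: multi-component structures are stripped to
their largest carbon-containing component, formal charges are neutralized
where a proton can be added or removed without touching connectivity, and
the result is re-canonicalized.  Records whose components are all inorganic
are rejected.  Deduplication keeps the first occurrence of each canonical
structure, so the library size ``M`` always counts unique compounds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "CompoundSet",
    "CurationRejection",
    "EmptyLibraryError",
    "read_library",
    "curate",
    "deduplicate",
    "load_and_curate",
]


class EmptyLibraryError(ValueError):
    """Raised when a library contains no usable record."""


class CurationRejection(Exception):
    """A record that cannot be curated; carries a machine-readable reason."""

    def __init__(self, reason: str, smiles: str):
        self.reason = reason
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier plus raw and curated structure strings."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    n_heavy_atoms: int
    n_rings: int

    def mol(self) -> Chem.Mol:
        """Return the RDKit molecule for the curated structure."""
        m = Chem.MolFromSmiles(self.smiles_canonical)
        if m is None:  # pragma: no cover - guarded by construction
            raise ValueError(f"stored SMILES no longer parses: {self.smiles_canonical}")
        return m


@dataclass
class CompoundSet:
    """An ordered, named collection of curated molecule records."""

    name: str
    records: list[MoleculeRecord] = field(default_factory=list)
    n_skipped: int = 0
    n_rejected: int = 0

    @property
    def size_M(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)


def _iter_smi(path: str) -> Iterator[tuple[str, Optional[str]]]:
    with open(path) as fh:
        row = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            row += 1
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
            yield smiles, ident if ident is not None else f"row{row}"


def _iter_sdf(path: str) -> Iterator[tuple[str, Optional[str]]]:
    suppl = Chem.SDMolSupplier(path, sanitize=True)
    for k, mol in enumerate(suppl, start=1):
        if mol is None:
            yield "", f"row{k}"  # unparseable; counted as skipped downstream
            continue
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        yield Chem.MolToSmiles(mol), title.strip() or f"row{k}"


def read_library(path: str, format: Optional[str] = None, name: Optional[str] = None) -> CompoundSet:
    """Read a raw library; one record per parseable entry, order preserved.

    ``format`` is ``"smi"`` or ``"sdf"``; inferred from the extension when
    omitted.  Unparseable records are skipped and counted in
    ``CompoundSet.n_skipped``.  Records are *not* curated here.
    """
    if not os.path.exists(path):
        raise IOError(f"library file not found: {path}")
    if format is None:
        format = "sdf" if path.lower().endswith((".sdf", ".mol")) else "smi"
    if format not in ("smi", "sdf"):
        raise ValueError(f"unknown format {format!r}")
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]

    reader = _iter_sdf(path) if format == "sdf" else _iter_smi(path)
    out = CompoundSet(name=name)
    for smiles, ident in reader:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            out.n_skipped += 1
            continue
        out.records.append(
            MoleculeRecord(
                id=ident or "?",
                smiles_raw=smiles,
                smiles_canonical=Chem.MolToSmiles(mol),
                n_heavy_atoms=mol.GetNumHeavyAtoms(),
                n_rings=rdMolDescriptors.CalcNumRings(mol),
            )
        )
    if not out.records:
        raise EmptyLibraryError(f"no parseable records in {path}")
    return out


_UNCHARGER = rdMolStandardize.Uncharger()


def curate(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize one record; raise :class:`CurationRejection` when impossible.

    Steps: split into connected components; keep the component with the most
    heavy atoms that contains at least one carbon (ties broken by the
    lexicographically smallest canonical SMILES); neutralize formal charges
    where a proton can be added/removed without changing connectivity;
    re-canonicalize.  Idempotent on its own output.
    """
    mol = Chem.MolFromSmiles(record.smiles_raw)
    if mol is None:
        mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise CurationRejection("unparseable", record.smiles_raw)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        raise CurationRejection("no_carbon_component", record.smiles_raw)
    best = min(organic, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))

    neutral = _UNCHARGER.uncharge(best)
    canonical = Chem.MolToSmiles(neutral)
    final = Chem.MolFromSmiles(canonical)
    if final is None:  # pragma: no cover - uncharger output always parses
        raise CurationRejection("standardization_failed", record.smiles_raw)
    return replace(
        record,
        smiles_canonical=Chem.MolToSmiles(final),
        n_heavy_atoms=final.GetNumHeavyAtoms(),
        n_rings=rdMolDescriptors.CalcNumRings(final),
    )


def deduplicate(cset: CompoundSet) -> CompoundSet:
    """Keep the first record per distinct canonical SMILES."""
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    for rec in cset.records:
        if rec.smiles_canonical in seen:
            continue
        seen.add(rec.smiles_canonical)
        kept.append(rec)
    if not kept:
        raise EmptyLibraryError(f"library {cset.name!r} is empty after deduplication")
    return CompoundSet(name=cset.name, records=kept,
                       n_skipped=cset.n_skipped, n_rejected=cset.n_rejected)


def load_and_curate(path: str, format: Optional[str] = None, name: Optional[str] = None) -> CompoundSet:
    """Full intake pipeline: read, curate (dropping rejections), deduplicate."""
    raw = read_library(path, format=format, name=name)
    return curate_set(raw)


def curate_set(raw: CompoundSet) -> CompoundSet:
    """Curate every record of a set, counting rejections, then deduplicate."""
    out = CompoundSet(name=raw.name, n_skipped=raw.n_skipped)
    for rec in raw.records:
        try:
            out.records.append(curate(rec))
        except CurationRejection:
            out.n_rejected += 1
    if not out.records:
        raise EmptyLibraryError(f"library {raw.name!r} is empty after curation")
    return deduplicate(out)


def write_smiles(records: Iterable[MoleculeRecord], path: str) -> None:
    """Write records as ``SMILES<TAB>ID`` lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles_canonical}\t{rec.id}\n")
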