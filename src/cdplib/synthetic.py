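"""Synthetic compound libraries with exactly known chemotype populations.

Test libraries are built from a shipped pool of 124 curated ring systems
(each already a pure framework: no terminal atoms to prune) decorated with
side chains drawn from a fixed menu of acyclic substituents.  Because a
purely acyclic substituent can neither create nor destroy a ring, the
chemotype of every decorated molecule is, by construction, the chemotype of
its bare scaffold — the generator's ground truth is exact, not statistical.
Ring-free members are simple heteroalkyl chains and all map to the shared
``ACYCLIC`` chemotype.

The chemotype population is controlled directly: an explicit per-scaffold
count list, a uniform split, or a Zipf law ``count_i ∝ i^(-s)`` whose
exponent tunes how concentrated the library is (larger s → fewer dominant
chemotypes → lower scaffold diversity).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol, rdMolDescriptors

from .chemotypes import ACYCLIC, extract_chemotype
from .io import CompoundSet, MoleculeRecord

__all__ = ["LibrarySpec", "generate_library", "scaffold_pool", "SUBSTITUENTS"]

#: acyclic substituents; attachment atom is the first atom of each SMILES.
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "F", "Cl", "Br", "O", "OC",
    "OCC", "N", "NC", "N(C)C", "C#N", "C(F)(F)F", "CO", "CCO", "S", "SC",
)

_CHAIN_ATOMS = ("C", "C", "C", "O", "N")  # biased toward carbon


class InfeasibleSpecError(ValueError):
    """More unique molecules demanded than the spec can construct."""


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for one synthetic library.

    ``count_distribution`` is ``"uniform"``, ``("zipf", s)`` with s > 0, or
    an explicit list of per-scaffold counts.  With a nonzero
    ``acyclic_fraction`` f, ``round(f * n_molecules)`` molecules are acyclic
    and the remainder is distributed over the scaffolds (explicit counts
    must then sum to the cyclic remainder).
    """

    n_scaffolds: int
    n_molecules: int
    count_distribution: Union[str, tuple[str, float], Sequence[int]] = "uniform"
    acyclic_fraction: float = 0.0
    decoration: int = 8
    seed: int = 0
    name: str = "synthetic"


@lru_cache(maxsize=1)
def scaffold_pool() -> tuple[str, ...]:
    """The shipped pool of framework-stable ring systems (canonical SMILES)."""
    text = (importlib.resources.files("cdplib") / "data" / "scaffold_pool.smi").read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


def _scaffold_counts(spec: LibrarySpec, n_cyclic: int) -> list[int]:
    dist = spec.count_distribution
    k = spec.n_scaffolds
    if isinstance(dist, str) and dist == "uniform":
        base, rem = divmod(n_cyclic, k)
        return [base + (1 if i < rem else 0) for i in range(k)]
    if isinstance(dist, tuple) and dist[0] == "zipf":
        s = float(dist[1])
        if s <= 0:
            raise ValueError("zipf exponent must be > 0")
        w = np.arange(1, k + 1, dtype=float) ** (-s)
        raw = w / w.sum() * (n_cyclic - k)  # reserve 1 per scaffold
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        for i in np.argsort(-remainder)[: n_cyclic - k - counts.sum()]:
            counts[i] += 1
        return (counts + 1).tolist()
    counts = [int(c) for c in dist]  # explicit list
    if len(counts) != k:
        raise ValueError(f"explicit counts: expected {k} entries, got {len(counts)}")
    if sum(counts) != n_cyclic:
        raise ValueError(f"explicit counts sum to {sum(counts)}, expected {n_cyclic}")
    if any(c < 1 for c in counts):
        raise ValueError("explicit counts must be >= 1")
    return counts


def _attach(scaffold: Chem.Mol, decorations: list[tuple[int, str]]) -> Optional[str]:
    """Attach substituents (atom index, substituent SMILES) by single bonds."""
    rw = RWMol(scaffold)
    for pos, sub in decorations:
        frag = Chem.MolFromSmiles(sub)
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag)
        rw.AddBond(pos, offset, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _decorated_series(scaffold_smiles: str, count: int, max_subs: int,
                      rng: np.random.Generator, max_tries: int = 400) -> list[str]:
    """``count`` unique molecules sharing one scaffold's chemotype."""
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    sites = [a.GetIdx() for a in scaffold.GetAtoms() if a.GetTotalNumHs() >= 1]
    out: list[str] = [Chem.MolToSmiles(scaffold)]  # the bare framework itself
    seen = set(out)
    tries = 0
    while len(out) < count and tries < max_tries * count:
        tries += 1
        k = int(rng.integers(1, max(2, min(max_subs, len(sites)) + 1)))
        pos = rng.choice(len(sites), size=min(k, len(sites)), replace=False)
        decorations = [(sites[p], SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))])
                       for p in pos]
        smi = _attach(scaffold, decorations)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    if len(out) < count:
        raise InfeasibleSpecError(
            f"could not build {count} unique molecules on scaffold {scaffold_smiles!r}")
    return out[:count]


def _acyclic_series(count: int, rng: np.random.Generator, max_tries: int = 400) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(out) < count and tries < max_tries * count:
        tries += 1
        length = int(rng.integers(3, 10))
        atoms = ["C"]
        for _ in range(length - 2):
            nxt = _CHAIN_ATOMS[int(rng.integers(len(_CHAIN_ATOMS)))]
            if atoms[-1] in ("O", "N") and nxt in ("O", "N"):
                nxt = "C"  # avoid heteroatom-heteroatom chains
            atoms.append(nxt)
        atoms.append("C")
        smi = Chem.CanonSmiles("".join(atoms))
        if smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    if len(out) < count:
        raise InfeasibleSpecError(f"could not build {count} unique acyclic molecules")
    return out


def generate_library(spec: LibrarySpec) -> tuple[CompoundSet, dict[str, str]]:
    """Build a synthetic library; returns (compound set, id -> chemotype key).

    Reproducible: a fixed spec (including seed) yields byte-identical SMILES.
    """
    pool = scaffold_pool()
    if spec.n_scaffolds > len(pool):
        raise InfeasibleSpecError(
            f"n_scaffolds={spec.n_scaffolds} exceeds pool size {len(pool)}")
    if not 0.0 <= spec.acyclic_fraction <= 1.0:
        raise ValueError("acyclic_fraction must be in [0, 1]")
    n_acyclic = int(round(spec.acyclic_fraction * spec.n_molecules))
    n_cyclic = spec.n_molecules - n_acyclic
    if n_cyclic < spec.n_scaffolds:
        raise InfeasibleSpecError("fewer cyclic molecules than scaffolds")

    rng = np.random.default_rng(spec.seed)
    scaffold_idx = rng.choice(len(pool), size=spec.n_scaffolds, replace=False)
    counts = _scaffold_counts(spec, n_cyclic)

    # Pair the most populated chemotypes with the scaffolds offering the most
    # substitution sites, so large analog series are always constructible.
    def _n_sites(idx: int) -> int:
        mol = Chem.MolFromSmiles(pool[int(idx)])
        return sum(1 for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1)

    by_capacity = sorted(scaffold_idx.tolist(), key=lambda i: (-_n_sites(i), i))

    records: list[MoleculeRecord] = []
    truth: dict[str, str] = {}
    k = 0
    for count, idx in zip(sorted(counts, reverse=True), by_capacity):
        scaffold_smiles = pool[int(idx)]
        key = extract_chemotype(scaffold_smiles).key
        for smi in _decorated_series(scaffold_smiles, count, spec.decoration, rng):
            k += 1
            mol = Chem.MolFromSmiles(smi)
            rec = MoleculeRecord(id=f"{spec.name}-{k:05d}", smiles_raw=smi,
                                 smiles_canonical=smi,
                                 n_heavy_atoms=mol.GetNumHeavyAtoms(),
                                 n_rings=rdMolDescriptors.CalcNumRings(mol))
            records.append(rec)
            truth[rec.id] = key
    for smi in _acyclic_series(n_acyclic, rng) if n_acyclic else []:
        k += 1
        mol = Chem.MolFromSmiles(smi)
        rec = MoleculeRecord(id=f"{spec.name}-{k:05d}", smiles_raw=smi,
                             smiles_canonical=smi,
                             n_heavy_atoms=mol.GetNumHeavyAtoms(),
                             n_rings=0)
        records.append(rec)
        truth[rec.id] = ACYCLIC
    return CompoundSet(name=spec.name, records=records), truth


def write_ground_truth(truth: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchemotype_key\n")
        for ident, key in truth.items():
            fh.write(f"{ident}\t{key}\n")
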