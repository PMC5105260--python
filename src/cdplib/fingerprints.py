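"""Intra-library fingerprint similarity distributions.

Structural diversity of a library is summarized by the distribution of
pairwise Tanimoto similarities over all M*(M-1)/2 unordered compound pairs,
computed on MACCS structural keys (166 bits) or on Morgan/extended-
connectivity fingerprints of diameter 4 (ECFP4) hashed to 2048 bits.  The
median of the MACCS/Tanimoto distribution is the fingerprint axis of the
consensus diversity plot: a *low* median similarity means a *diverse*
library.

Fingerprints come from RDKit; note that RDKit's MACCS implementation uses a
167-slot vector whose bit 0 is never set, so indices match the standard
1-based key numbering.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .io import CompoundSet, MoleculeRecord

__all__ = ["Fingerprint", "SimilaritySummary", "fingerprint", "tanimoto",
           "pairwise_similarities", "intra_similarity_summary",
           "ECFP4_NBITS", "FINGERPRINT_KINDS"]

ECFP4_NBITS = 2048
FINGERPRINT_KINDS = ("maccs166", "ecfp4")

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ECFP4_NBITS)


@dataclass(frozen=True)
class Fingerprint:
    """A binary fingerprint as a frozenset of set-bit indices."""

    kind: str
    bits: frozenset[int]
    length: int


def fingerprint(record: MoleculeRecord | str, kind: str = "maccs166") -> Fingerprint:
    """Compute a MACCS-keys or ECFP4 fingerprint for a curated molecule."""
    if kind not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    mol = Chem.MolFromSmiles(record) if isinstance(record, str) else record.mol()
    if mol is None:
        raise ValueError(f"unparseable SMILES: {record!r}")
    if kind == "maccs166":
        bv = MACCSkeys.GenMACCSKeys(mol)
        length = 167  # slot 0 unused; keys are 1..166
    else:
        bv = _morgan.GetFingerprint(mol)
        length = ECFP4_NBITS
    return Fingerprint(kind=kind, bits=frozenset(bv.GetOnBits()), length=length)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over set bits.

    Two empty fingerprints score 0 (treated as maximally dissimilar, with a
    warning) rather than 1: a featureless pair carries no evidence of
    structural identity.
    """
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass(frozen=True)
class SimilaritySummary:
    """Seven-number summary of an intra-library similarity distribution."""

    set_name: str
    kind: str
    n_pairs: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    sd: float
    sd_defined: bool = True


def pairwise_similarities(fps: list[Fingerprint]) -> np.ndarray:
    """All unordered-pair Tanimoto similarities, in (i, j) lexicographic order."""
    m = len(fps)
    bits = [fp.bits for fp in fps]
    sizes = np.array([len(b) for b in bits])
    out = np.empty(m * (m - 1) // 2)
    k = 0
    for i, j in itertools.combinations(range(m), 2):
        inter = len(bits[i] & bits[j])
        union = sizes[i] + sizes[j] - inter
        out[k] = inter / union if union else 0.0
        k += 1
    return out


def summarize_similarities(values: np.ndarray, set_name: str, kind: str) -> SimilaritySummary:
    """Seven-number summary; quartiles by linear interpolation, sd with n-1."""
    if values.size == 0:
        raise ValueError("no pairs to summarize")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    sd_defined = values.size > 1
    sd = float(np.std(values, ddof=1)) if sd_defined else 0.0
    return SimilaritySummary(
        set_name=set_name, kind=kind, n_pairs=int(values.size),
        min=float(values.min()), q1=float(q1), median=float(med),
        mean=float(values.mean()), q3=float(q3), max=float(values.max()),
        sd=sd, sd_defined=sd_defined,
    )


def intra_similarity_summary(cset: CompoundSet, kind: str = "maccs166") -> SimilaritySummary:
    """Summarize the full pairwise similarity distribution of one library.

    Enumerates every unordered pair (no sampling); requires M >= 2.
    """
    if len(cset) < 2:
        raise ValueError(f"need at least 2 molecules in {cset.name!r}, got {len(cset)}")
    fps = [fingerprint(rec, kind=kind) for rec in cset]
    values = pairwise_similarities(fps)
    return summarize_similarities(values, cset.name, kind)


def write_similarity_tsv(summaries: Iterable[SimilaritySummary], path: str) -> None:
    """Table-style dump: Min., 1st Qu., Median, Mean, 3rd Qu., Max., SD."""
    cols = ["set_name", "kind", "n_pairs", "Min.", "1st Qu.", "Median",
            "Mean", "3rd Qu.", "Max.", "SD"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            fh.write("\t".join([
                s.set_name, s.kind, str(s.n_pairs),
                *(f"{v:.4f}" for v in (s.min, s.q1, s.median, s.mean, s.q3, s.max, s.sd)),
            ]) + "\n")
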