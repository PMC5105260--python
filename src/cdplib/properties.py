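"""Physicochemical property profiles and inter-/intra-set distances.

Six descriptors of pharmaceutical relevance are computed per molecule:
hydrogen-bond donors (HBD), hydrogen-bond acceptors (HBA), Wildman–Crippen
logP, molecular weight (Da), Ertl topological polar surface area (Å²) and
rotatable-bond count (RTB).

The property diversity of a library, and the dissimilarity between two
libraries, is the mean Euclidean distance

    I_uv = (1 / (U * V)) * sum_i sum_j ||x_i - y_j||

over all ordered pairs of property vectors; with u = v (self-pairs
included, divisor U^2) this is the intra-set distance.  Because MW and TPSA
dwarf the count descriptors on their raw scales, columns are z-scored
against the pooled population of all compared sets before distances are
taken (disable with ``scale=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .io import CompoundSet, MoleculeRecord

__all__ = ["PROPERTY_NAMES", "PropertyVector", "SetDistance",
           "compute_properties", "property_matrix", "standardize",
           "set_distance", "distance_matrix"]

PROPERTY_NAMES = ("hbd", "hba", "logp", "mw", "tpsa", "rtb")


@dataclass(frozen=True)
class PropertyVector:
    """One molecule's six-descriptor profile."""

    hbd: int
    hba: int
    logp: float
    mw: float
    tpsa: float
    rtb: int

    def as_array(self) -> np.ndarray:
        return np.array([self.hbd, self.hba, self.logp, self.mw, self.tpsa, self.rtb],
                        dtype=float)


@dataclass(frozen=True)
class SetDistance:
    """Mean pairwise Euclidean property distance between two libraries."""

    set_u: str
    set_v: str
    distance: float
    is_intra: bool


def compute_properties(record: MoleculeRecord | str) -> PropertyVector:
    """Descriptors for one curated molecule (RDKit implementations)."""
    mol = Chem.MolFromSmiles(record) if isinstance(record, str) else record.mol()
    if mol is None:
        raise ValueError(f"unparseable SMILES: {record!r}")
    return PropertyVector(
        hbd=int(Descriptors.NumHDonors(mol)),
        hba=int(Descriptors.NumHAcceptors(mol)),
        logp=float(Crippen.MolLogP(mol)),
        mw=float(Descriptors.MolWt(mol)),
        tpsa=float(Descriptors.TPSA(mol)),
        rtb=int(Descriptors.NumRotatableBonds(mol)),
    )


def property_matrix(cset: CompoundSet) -> np.ndarray:
    """(M, 6) raw descriptor matrix in record order."""
    return np.vstack([compute_properties(rec).as_array() for rec in cset])


def standardize(matrices: list[np.ndarray]) -> tuple[list[np.ndarray], dict]:
    """Z-score each column against the pooled rows of all given matrices.

    Returns the scaled matrices and the scaling parameters
    ``{"mean": ..., "sd": ..., "constant_columns": [...]}``.  Zero-variance
    columns are centered but divided by 1 and flagged.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    pooled = np.vstack(matrices)
    if pooled.shape[0] < 2:
        raise ValueError("pooled population must have at least 2 rows")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    constant = np.where(sd == 0)[0].tolist()
    divisor = np.where(sd == 0, 1.0, sd)
    scaled = [(m - mean) / divisor for m in matrices]
    params = {"mean": mean, "sd": sd, "constant_columns": constant}
    return scaled, params


def set_distance(Du: np.ndarray, Dv: np.ndarray,
                 name_u: str = "u", name_v: str = "v",
                 exclude_self: bool = False) -> SetDistance:
    """Mean Euclidean distance over all U*V ordered row pairs.

    For the intra-set case (``Du is Dv`` or equal contents) the same formula
    applies verbatim: self-pairs (distance 0) are included and the divisor is
    U^2, unless ``exclude_self`` is set.
    """
    Du = np.atleast_2d(np.asarray(Du, dtype=float))
    Dv = np.atleast_2d(np.asarray(Dv, dtype=float))
    if Du.shape[1] != Dv.shape[1]:
        raise ValueError(f"column mismatch: {Du.shape[1]} vs {Dv.shape[1]}")
    d = cdist(Du, Dv, metric="euclidean")
    is_intra = name_u == name_v or (Du.shape == Dv.shape and np.array_equal(Du, Dv))
    if exclude_self and is_intra:
        u = Du.shape[0]
        if u < 2:
            raise ValueError("exclude_self needs at least 2 rows")
        np.fill_diagonal(d, 0.0)
        mean = float(np.sort(d, axis=None).sum() / (u * (u - 1)))
        return SetDistance(name_u, name_v, mean, True)
    # summing the sorted multiset makes the result exactly symmetric in (u, v)
    mean = float(np.sort(d, axis=None).sum() / d.size)
    return SetDistance(name_u, name_v, mean, is_intra)


def distance_matrix(matrices: dict[str, np.ndarray], scale: bool = True) -> "pd.DataFrame":
    """Square I_uv matrix over named sets; diagonal holds intra-set values."""
    import pandas as pd

    names = list(matrices)
    mats = [matrices[n] for n in names]
    if scale:
        mats, _ = standardize(mats)
    out = np.zeros((len(names), len(names)))
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j < i:
                out[i, j] = out[j, i]
                continue
            out[i, j] = set_distance(mats[i], mats[j], ni, nj).distance
    return pd.DataFrame(out, index=names, columns=names)
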