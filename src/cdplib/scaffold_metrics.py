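"""Scaffold-diversity statistics: count ratios, CSR curves, AUC, F50, entropy.

The cyclic-system recovery (CSR) curve plots the cumulative fraction of
compounds (y) recovered by the top fraction of chemotypes (x), chemotypes
sorted by descending population.  A library in which every molecule carries
its own chemotype traces the diagonal (trapezoidal AUC exactly 0.5, maximum
diversity); as compounds concentrate into few chemotypes the curve bulges
toward the top-left and the AUC approaches 1 (minimum diversity).  F50 is
the fraction of chemotypes needed to cover half the compounds — high F50
means high diversity, the opposite reading of AUC.

The Shannon entropy of the chemotype population distribution,
``SE = -sum p_i log2 p_i`` with ``p_i = c_i / P``, ranges from 0 (all
compounds in one chemotype) to ``log2 n`` (even spread over n chemotypes).
The scaled entropy ``SSE = SE / log2 n`` normalizes that to [0, 1] so
different top-n choices are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .chemotypes import ChemotypeTable

__all__ = [
    "CSRCurve", "EntropyResult", "ScaffoldSummary",
    "csr_curve", "auc", "f50",
    "shannon_entropy", "scaled_shannon_entropy", "sse_profile",
    "summarize_scaffolds", "count_ratios",
    "DEFAULT_SSE_GRID",
]

#: top-n grid used for SSE profiles: the n most populated chemotypes.
DEFAULT_SSE_GRID: tuple[int, ...] = tuple(range(5, 75, 5))


@dataclass
class CSRCurve:
    """An ordered CSR curve from (0, 0) to (1, 1).

    ``x[k] = k / N`` and ``y[k]`` is the fraction of compounds held by the
    ``k`` most populated chemotypes.
    """

    x: np.ndarray
    y: np.ndarray
    convention: str = "trapezoid"

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy over the ``n_selected`` most populated chemotypes."""

    n_top: int          # requested n
    n_selected: int     # min(n_top, N) actually used
    se: float           # bits
    sse: float          # se / log2(n_selected); 0 when n_selected == 1


@dataclass(frozen=True)
class ScaffoldSummary:
    """All per-library scaffold-diversity numbers (full precision)."""

    set_name: str
    N: int
    M: int
    N_sing: int
    N_over_M: float
    Nsing_over_N: float
    Nsing_over_M: float
    auc: float
    f50: float


def _sorted_counts(table: ChemotypeTable) -> np.ndarray:
    table.validate()
    return np.array([c for _, c in table.sorted_counts()], dtype=np.int64)


def csr_curve(table: ChemotypeTable, convention: str = "trapezoid") -> CSRCurve:
    """Build the CSR curve of a chemotype table, anchored at (0, 0)."""
    if convention not in ("trapezoid", "staircase"):
        raise ValueError(f"unknown AUC convention {convention!r}")
    counts = _sorted_counts(table)
    n, m = len(counts), counts.sum()
    x = np.arange(n + 1, dtype=float) / n
    y = np.concatenate([[0.0], np.cumsum(counts) / m])
    return CSRCurve(x=x, y=y, convention=convention)


def auc(curve: CSRCurve) -> float:
    """Area under a CSR curve.

    Trapezoid (default) integrates the piecewise-linear curve including the
    (0, 0) anchor, which makes the all-singleton diagonal score exactly 0.5.
    Staircase sums ``(1/N) * y_right`` per chemotype instead.
    """
    if curve.convention == "trapezoid":
        return float(np.trapezoid(curve.y, curve.x))
    dx = np.diff(curve.x)
    return float(np.sum(dx * curve.y[1:]))


def f50(table: ChemotypeTable) -> float:
    """Fraction of chemotypes covering at least 50% of the compounds.

    Discrete rule: with counts sorted descending, the smallest k whose
    cumulative compound fraction reaches one half, divided by N.  No
    interpolation between chemotypes.
    """
    counts = _sorted_counts(table)
    m = counts.sum()
    cum = np.cumsum(counts)
    k_star = int(np.searchsorted(cum * 2, m, side="left")) + 1
    return k_star / len(counts)


def shannon_entropy(counts: Iterable[int]) -> EntropyResult:
    """Shannon entropy (bits) of a chemotype population distribution."""
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("empty count list")
    if np.any(c < 1):
        raise ValueError("all counts must be >= 1")
    p = c / c.sum()
    se = float(-np.sum(p * np.log2(p)) + 0.0)  # +0.0 normalizes -0.0
    n = int(c.size)
    sse = 0.0 if n == 1 else se / float(np.log2(n))
    return EntropyResult(n_top=n, n_selected=n, se=se, sse=sse)


def scaled_shannon_entropy(table: ChemotypeTable, n_top: int) -> EntropyResult:
    """SSE over the ``n_top`` most populated chemotypes.

    ``n_top`` is clamped to the number of chemotypes actually present; the
    population P is renormalized to the selected chemotypes.  A single
    selected chemotype has SSE 0 by convention (log2(1) = 0 denominator).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    counts = _sorted_counts(table)
    selected = counts[: min(n_top, len(counts))]
    res = shannon_entropy(selected)
    return EntropyResult(n_top=n_top, n_selected=res.n_selected, se=res.se, sse=res.sse)


def sse_profile(table: ChemotypeTable, n_values: Sequence[int] = DEFAULT_SSE_GRID) -> list[EntropyResult]:
    """SSE at each top-n of a grid (default 5, 10, ..., 70)."""
    if not n_values:
        raise ValueError("n_values must be nonempty")
    return [scaled_shannon_entropy(table, n) for n in n_values]


def count_ratios(N: int, M: int, N_sing: int) -> dict[str, float]:
    """Chemotype/singleton count ratios, rounded to 3 decimals (half-even).

    Exact rational arithmetic before rounding, so printed ratios are
    reproducible from integer counts alone.
    """
    if not (0 <= N_sing <= N <= M) or N < 1:
        raise ValueError("need 0 <= N_sing <= N <= M and N >= 1")
    return {
        "N_over_M": float(round(Fraction(N, M), 3)),
        "Nsing_over_N": float(round(Fraction(N_sing, N), 3)),
        "Nsing_over_M": float(round(Fraction(N_sing, M), 3)),
    }


def summarize_scaffolds(table: ChemotypeTable, convention: str = "trapezoid") -> ScaffoldSummary:
    """Compute the full scaffold-diversity summary for one library."""
    table.validate()
    n, m, n_sing = table.N, table.M, table.N_sing
    return ScaffoldSummary(
        set_name=table.set_name,
        N=n, M=m, N_sing=n_sing,
        N_over_M=n / m,
        Nsing_over_N=n_sing / n,
        Nsing_over_M=n_sing / m,
        auc=auc(csr_curve(table, convention=convention)),
        f50=f50(table),
    )


def write_scaffold_summary_tsv(summaries: list[ScaffoldSummary],
                               sse_rows: dict[str, list[EntropyResult]],
                               path: str) -> None:
    """One row per library: counts, ratios (3 decimals), AUC, F50, SSE grid."""
    grids = {tuple(r.n_top for r in rows) for rows in sse_rows.values()}
    grid = sorted(grids.pop()) if len(grids) == 1 else sorted(DEFAULT_SSE_GRID)
    header = ["set_name", "N", "M", "N_sing", "N_over_M", "Nsing_over_N",
              "Nsing_over_M", "AUC", "F50"] + [f"SSE{n}" for n in grid]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s in summaries:
            sse_by_n = {r.n_top: r.sse for r in sse_rows.get(s.set_name, [])}
            row = [s.set_name, str(s.N), str(s.M), str(s.N_sing),
                   f"{round(s.N_over_M, 3):.3f}", f"{round(s.Nsing_over_N, 3):.3f}",
                   f"{round(s.Nsing_over_M, 3):.3f}", f"{round(s.auc, 3):.3f}",
                   f"{round(s.f50, 3):.3f}"]
            row += [f"{round(sse_by_n[n], 3):.3f}" if n in sse_by_n else "" for n in grid]
            fh.write("\t".join(row) + "\n")


def write_csr_tsv(curves: dict[str, CSRCurve], path: str) -> None:
    """Long-format curve dump (set_name, x, y) for external plotting."""
    with open(path, "w") as fh:
        fh.write("set_name\tx\ty\n")
        for name, curve in curves.items():
            for xv, yv in zip(curve.x, curve.y):
                fh.write(f"{name}\t{xv:.10g}\t{yv:.10g}\n")
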