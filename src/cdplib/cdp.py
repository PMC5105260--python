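"""Consensus Diversity Plot assembly, quadrant classification and rendering.

Each library becomes one point: median intra-set fingerprint similarity on
the x-axis (lower = more diverse), a scaffold-diversity metric (AUC, F50 or
SSE at a chosen top-n) on the y-axis, intra-set property distance mapped to
a green→orange→red color ramp (red = most property-diverse among the
compared sets), and library size mapped to point area.  Dashed threshold
lines split the plane into four quadrants:

* red — high fingerprint AND high scaffold diversity,
* white — low on both,
* blue — high fingerprint diversity only,
* yellow — high scaffold diversity only.

For AUC a *low* value means high scaffold diversity; for F50 and SSE a
*high* value does.  Thresholds may be fixed numbers (the conventional AUC
cut is 0.75) or ``"median"``, resolved to the median of that metric across
the compared sets.  A value exactly on a threshold classifies as LOW
diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["CDPRecord", "ThresholdConfig", "ResolvedThresholds",
           "assemble_records", "resolve_thresholds", "classify_quadrant",
           "classify_all", "render_cdp", "render_composite", "QUADRANTS"]

QUADRANTS = ("both_high", "both_low", "fp_only", "scaffold_only", "unclassified")

#: metrics for which a HIGH value means HIGH scaffold diversity
_HIGH_IS_DIVERSE = {"f50": True, "sse": True, "auc": False}


@dataclass
class CDPRecord:
    """One library's consensus coordinates."""

    set_name: str
    x_fp: float             # median intra-set Tanimoto similarity
    y_metric: str           # auc | f50 | sse
    y_value: float
    prop_diversity: float   # intra-set property distance
    size_M: int
    quadrant: str = "unclassified"


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold specification; values are numbers or the string 'median'."""

    y_metric: str = "auc"
    x_threshold: float | str = "median"
    y_threshold: float | str = 0.75

    @property
    def y_direction_high_is_diverse(self) -> bool:
        try:
            return _HIGH_IS_DIVERSE[self.y_metric]
        except KeyError:
            raise ValueError(f"unknown y_metric {self.y_metric!r}") from None


@dataclass(frozen=True)
class ResolvedThresholds:
    y_metric: str
    x_threshold: float
    y_threshold: float
    y_direction_high_is_diverse: bool


def assemble_records(scaffold: dict[str, float], fingerprint_median: dict[str, float],
                     prop_intra: dict[str, float], sizes: dict[str, int],
                     y_metric: str = "auc") -> list[CDPRecord]:
    """Join per-set metric dictionaries into CDP records.

    Every set present in ``scaffold`` must appear in all other mappings;
    a missing metric raises an error naming the offending set.
    """
    if y_metric not in _HIGH_IS_DIVERSE:
        raise ValueError(f"unknown y_metric {y_metric!r}")
    records = []
    for name, y in scaffold.items():
        for label, mapping in (("fingerprint", fingerprint_median),
                               ("property", prop_intra), ("size", sizes)):
            if name not in mapping:
                raise KeyError(f"set {name!r} lacks a {label} summary")
        records.append(CDPRecord(
            set_name=name, x_fp=fingerprint_median[name], y_metric=y_metric,
            y_value=y, prop_diversity=prop_intra[name], size_M=sizes[name],
        ))
    return records


def resolve_thresholds(records: Sequence[CDPRecord], config: ThresholdConfig) -> ResolvedThresholds:
    """Turn 'median' placeholders into numbers over the compared sets."""
    if not records:
        raise ValueError("no records")
    if len(records) == 1 and "median" in (config.x_threshold, config.y_threshold):
        import warnings
        warnings.warn("median threshold over a single record is degenerate")

    def _resolve(spec: float | str, values: list[float]) -> float:
        if spec == "median":
            return float(np.median(values))
        return float(spec)

    return ResolvedThresholds(
        y_metric=config.y_metric,
        x_threshold=_resolve(config.x_threshold, [r.x_fp for r in records]),
        y_threshold=_resolve(config.y_threshold, [r.y_value for r in records]),
        y_direction_high_is_diverse=config.y_direction_high_is_diverse,
    )


def classify_quadrant(record: CDPRecord, thresholds: ResolvedThresholds) -> str:
    """Assign the four-quadrant label; ties at a threshold classify LOW."""
    fp_high = record.x_fp < thresholds.x_threshold  # low similarity = diverse
    if thresholds.y_direction_high_is_diverse:
        sc_high = record.y_value > thresholds.y_threshold
    else:
        sc_high = record.y_value < thresholds.y_threshold
    if fp_high and sc_high:
        return "both_high"
    if fp_high:
        return "fp_only"
    if sc_high:
        return "scaffold_only"
    return "both_low"


def classify_all(records: Sequence[CDPRecord], thresholds: ResolvedThresholds) -> list[CDPRecord]:
    return [replace(r, quadrant=classify_quadrant(r, thresholds)) for r in records]


_QUADRANT_TINTS = {"both_high": "#d6272822", "both_low": "#ffffff00",
                   "fp_only": "#1f77b422", "scaffold_only": "#ffdf0033"}

_Y_LABEL = {"auc": "CSR curve AUC (lower = more diverse)",
            "f50": "F50 (higher = more diverse)",
            "sse": "scaled Shannon entropy (higher = more diverse)"}


def _prop_colors(values: np.ndarray):
    """Green (least diverse) → orange/brown → red (most diverse), min–max scaled."""
    from matplotlib.colors import LinearSegmentedColormap, Normalize

    cmap = LinearSegmentedColormap.from_list(
        "cdp_prop", ["#2ca02c", "#b5651d", "#d62728"])
    span = values.max() - values.min()
    norm = Normalize(vmin=values.min(), vmax=values.max() if span > 0 else values.min() + 1)
    return cmap, norm


def _draw_panel(ax, records: Sequence[CDPRecord], thresholds: ResolvedThresholds,
                cmap, norm, title: Optional[str] = None):
    """Draw one CDP panel onto an axes; records must already be classified."""
    x = np.array([r.x_fp for r in records])
    y = np.array([r.y_value for r in records])
    prop = np.array([r.prop_diversity for r in records])
    sizes = np.array([r.size_M for r in records], dtype=float)
    areas = 40.0 + 360.0 * sizes / sizes.max()

    xt, yt = thresholds.x_threshold, thresholds.y_threshold
    xlim = (min(x.min(), xt) - 0.05, max(x.max(), xt) + 0.05)
    ylim = (min(y.min(), yt) - 0.05, max(y.max(), yt) + 0.05)
    hi = thresholds.y_direction_high_is_diverse

    def _tint(x0, x1, y0, y1, quad):
        ax.axhspan(y0, y1, xmin=(x0 - xlim[0]) / (xlim[1] - xlim[0]),
                   xmax=(x1 - xlim[0]) / (xlim[1] - xlim[0]),
                   facecolor=_QUADRANT_TINTS[quad], zorder=0)

    y_div = (yt, ylim[1]) if hi else (ylim[0], yt)     # scaffold-diverse half
    y_not = (ylim[0], yt) if hi else (yt, ylim[1])
    _tint(xlim[0], xt, *y_div, "both_high")
    _tint(xt, xlim[1], *y_not, "both_low")
    _tint(xlim[0], xt, *y_not, "fp_only")
    _tint(xt, xlim[1], *y_div, "scaffold_only")

    sc = ax.scatter(x, y, s=areas, c=prop, cmap=cmap, norm=norm,
                    edgecolors="black", linewidths=0.6, zorder=3)
    ax.axvline(xt, ls="--", color="gray", lw=1)
    ax.axhline(yt, ls="--", color="gray", lw=1)
    for r, xv, yv in zip(records, x, y):
        ax.annotate(r.set_name, (xv, yv), textcoords="offset points",
                    xytext=(5, 5), fontsize=7)
    ax.set_xlim(*xlim)
    ax.set_ylim(*ylim)
    ax.set_xlabel("median Tanimoto similarity (lower = more diverse)")
    ax.set_ylabel(_Y_LABEL[thresholds.y_metric])
    ax.set_title(title or f"Consensus Diversity Plot ({thresholds.y_metric.upper()})")
    ax.text(0.01, 0.01,
            f"x threshold = {xt:.3f}; y threshold = {yt:.3f}; area ∝ M",
            transform=ax.transAxes, fontsize=7, color="dimgray")
    return sc


def _save(fig, out_plot: str, formats: Sequence[str]) -> list[str]:
    base = out_plot.rsplit(".", 1)[0] if out_plot.rsplit(".", 1)[-1] in ("svg", "png")         else out_plot
    written = []
    for fmt in formats:
        path = f"{base}.{fmt}"
        fig.savefig(path)
        written.append(path)
    return written


def render_cdp(records: Sequence[CDPRecord], thresholds: ResolvedThresholds,
               out_plot: str, out_table: Optional[str] = None,
               title: Optional[str] = None, formats: Sequence[str] = ("svg",)) -> list[str]:
    """Render the scatter plot (+ companion TSV); returns written file paths.

    Point area is proportional to library size (radius scales with sqrt(M));
    fill color encodes intra-set property distance on the green→red ramp.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("no records to plot")
    records = classify_all(records, thresholds)
    cmap, norm = _prop_colors(np.array([r.prop_diversity for r in records]))

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    sc = _draw_panel(ax, records, thresholds, cmap, norm, title=title)
    cb = fig.colorbar(sc, ax=ax)
    cb.set_label("intra-set property distance (red = more diverse)")
    fig.tight_layout()
    written = _save(fig, out_plot, formats)
    plt.close(fig)

    if out_table:
        write_records_tsv(records, thresholds, out_table)
        written.append(out_table)
    return written


def render_composite(panels: Sequence[tuple[Sequence[CDPRecord], ResolvedThresholds]],
                     out_plot: str, formats: Sequence[str] = ("svg",)) -> list[str]:
    """Tile several CDPs (one per scaffold metric) into one composite figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not panels:
        raise ValueError("no panels to plot")
    prop = np.array([r.prop_diversity for recs, _ in panels for r in recs])
    cmap, norm = _prop_colors(prop)
    fig, axes = plt.subplots(1, len(panels), figsize=(6.0 * len(panels), 5.5),
                             squeeze=False)
    sc = None
    for ax, (recs, thresholds) in zip(axes[0], panels):
        if not recs:
            raise ValueError("empty panel")
        sc = _draw_panel(ax, classify_all(recs, thresholds), thresholds, cmap, norm)
    cb = fig.colorbar(sc, ax=list(axes[0]))
    cb.set_label("intra-set property distance (red = more diverse)")
    written = _save(fig, out_plot, formats)
    plt.close(fig)
    return written


def write_records_tsv(records: Sequence[CDPRecord], thresholds: ResolvedThresholds,
                      path: str) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tx_fp\ty_metric\ty_value\tprop_diversity\tsize_M\t"
                 "quadrant\tx_threshold\ty_threshold\n")
        for r in records:
            fh.write(f"{r.set_name}\t{r.x_fp:.10g}\t{r.y_metric}\t{r.y_value:.10g}\t"
                     f"{r.prop_diversity:.10g}\t{r.size_M}\t{r.quadrant}\t"
                     f"{thresholds.x_threshold:.10g}\t{thresholds.y_threshold:.10g}\n")


def read_records_tsv(path: str) -> tuple[list[CDPRecord], Optional[ResolvedThresholds]]:
    """Round-trip reader for the companion TSV."""
    records, thresholds = [], None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(CDPRecord(
                set_name=f[idx["set_name"]], x_fp=float(f[idx["x_fp"]]),
                y_metric=f[idx["y_metric"]], y_value=float(f[idx["y_value"]]),
                prop_diversity=float(f[idx["prop_diversity"]]),
                size_M=int(f[idx["size_M"]]), quadrant=f[idx["quadrant"]],
            ))
            thresholds = ResolvedThresholds(
                y_metric=f[idx["y_metric"]],
                x_threshold=float(f[idx["x_threshold"]]),
                y_threshold=float(f[idx["y_threshold"]]),
                y_direction_high_is_diverse=_HIGH_IS_DIVERSE[f[idx["y_metric"]]],
            )
    return records, thresholds
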