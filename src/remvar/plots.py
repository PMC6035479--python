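"""Forest and variation-sources plots for reference effect measures.

Both displays put fixed effects and distribution-based variation sources on
a shared log-scaled odds-ratio axis.  Fixed effects are drawn as point +
whisker (OR with CI); variation sources (the random-intercept distribution
or an empirical risk distribution) are drawn as nested shaded bands whose
edges are REM values at a ladder of percentiles, darkening toward the
median.  The numbers bound to every glyph are exposed via the
``build_*_data`` functions so tests can assert on them without touching
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .measures import (
    EffectScale,
    EmpiricalRiskDistribution,
    RandomEffectDistribution,
    rem_empirical,
    rem_random,
)

__all__ = [
    "ForestRow",
    "DEFAULT_BAND_PERCENTILES",
    "build_forest_data",
    "forest_plot",
    "build_variation_data",
    "variation_sources_plot",
]

#: Upper percentiles of the shading ladder; each is mirrored below the median.
DEFAULT_BAND_PERCENTILES = (0.975, 0.90, 0.80, 0.70, 0.60, 0.50)


@dataclass
class ForestRow:
    """One display row: either a fixed effect or a REM band.

    Fixed-effect rows carry ``or_`` and ``ci``; band rows carry ``dist`` (a
    :class:`RandomEffectDistribution` or :class:`EmpiricalRiskDistribution`)
    plus an optional percentile ladder.
    """

    label: str
    kind: str  # "fixed" | "band"
    or_: float | None = None
    ci: tuple[float, float] | None = None
    dist: object | None = None
    percentiles: tuple[float, ...] = DEFAULT_BAND_PERCENTILES
    point: float | None = None  # e.g. REM(0.75) marker
    point_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("fixed", "band"):
            raise ValueError(f"row kind must be 'fixed' or 'band', got {self.kind!r}")
        if self.kind == "fixed":
            if self.or_ is None:
                raise ValueError(f"fixed-effect row {self.label!r} needs an odds ratio")
            vals = [self.or_, *(self.ci or ())]
            if any(v <= 0 for v in vals):
                raise ValueError("ratio-scale values must be positive")
        if self.kind == "band" and self.dist is None:
            raise ValueError(f"band row {self.label!r} needs a distribution")


def _band_edges(dist, percentiles) -> list[tuple[float, float, float]]:
    """(percentile, low, high) band triples on the ratio scale."""
    edges = []
    for p in sorted(percentiles, reverse=True):
        hi_a, lo_a = p, 1.0 - p
        if isinstance(dist, EmpiricalRiskDistribution):
            lo = rem_empirical(dist, lo_a) if lo_a > 0 else np.nan
            hi = rem_empirical(dist, hi_a)
        elif isinstance(dist, RandomEffectDistribution):
            lo = rem_random(dist, lo_a)
            hi = rem_random(dist, hi_a)
        else:
            raise TypeError(f"unsupported band distribution {type(dist).__name__}")
        edges.append((p, float(min(lo, hi)), float(max(lo, hi))))
    return edges


def build_forest_data(rows: list[ForestRow]) -> list[dict]:
    """Numbers bound to each forest-plot row (the testable data layer)."""
    if not rows:
        raise ValueError("forest plot needs at least one row")
    out = []
    for i, row in enumerate(rows):
        entry = {"label": row.label, "kind": row.kind, "y": len(rows) - 1 - i}
        if row.kind == "fixed":
            entry["or"] = float(row.or_)
            entry["ci"] = tuple(map(float, row.ci)) if row.ci else None
        else:
            entry["bands"] = _band_edges(row.dist, row.percentiles)
            entry["point"] = row.point
            entry["point_ci"] = row.point_ci
        out.append(entry)
    return out


def _draw_rows(ax, data, band_color):
    ymax = max(e["y"] for e in data)
    for entry in data:
        y = entry["y"]
        if entry["kind"] == "fixed":
            if entry["ci"]:
                ax.plot(entry["ci"], [y, y], color="0.2", lw=1.2, zorder=3)
            ax.plot([entry["or"]], [y], "s", color="0.1", ms=5, zorder=4)
        else:
            n = max(len(entry["bands"]), 1)
            for k, (_, lo, hi) in enumerate(entry["bands"]):
                alpha = 0.15 + 0.75 * (k + 1) / n  # darken toward the median
                ax.fill_betweenx(
                    [y - 0.3, y + 0.3], lo, hi,
                    color=band_color, alpha=alpha, linewidth=0, zorder=2,
                )
            if entry.get("point") is not None:
                if entry.get("point_ci"):
                    ax.plot(entry["point_ci"], [y, y], color="0.1", lw=1.2, zorder=4)
                ax.plot([entry["point"]], [y], "o", color="0.1", ms=5, zorder=5)
    ax.axvline(1.0, color="0.5", lw=0.8, ls="--", zorder=1)
    ax.set_xscale("log")
    ax.set_yticks([e["y"] for e in data])
    ax.set_yticklabels([e["label"] for e in data])
    ax.set_ylim(-0.7, ymax + 0.7)
    ax.set_xlabel("Odds ratio (log scale)")


def forest_plot(
    rows: list[ForestRow],
    path: str | None = None,
    band_color: str = "#3b6fb6",
    figsize: tuple[float, float] | None = None,
    dpi: int = 150,
) -> list[dict]:
    """Forest plot of fixed-effect ORs/CIs and shaded REM bands.

    Returns the plot-data layer; saves the figure if ``path`` is given
    (format chosen by extension: .png/.svg/.pdf).
    """
    data = build_forest_data(rows)
    fig, ax = plt.subplots(figsize=figsize or (7, 0.5 * len(rows) + 1.5))
    _draw_rows(ax, data, band_color)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return data


def build_variation_data(report) -> list[dict]:
    """Data layer for the variation-sources display of a :class:`REMReport`."""
    rows = []
    for src in report.sources:
        rows.append(
            ForestRow(
                label=src.label,
                kind="band",
                dist=src.dist,
                point=src.rem75.point if src.rem75 else None,
                point_ci=src.rem75.as_tuple() if src.rem75 else None,
            )
        )
    return build_forest_data(rows)


def variation_sources_plot(
    report,
    path: str | None = None,
    band_color: str = "#3b6fb6",
    figsize: tuple[float, float] | None = None,
    dpi: int = 150,
) -> list[dict]:
    """REM ranges for each variation source with REM(0.75) markers and CIs."""
    data = build_variation_data(report)
    fig, ax = plt.subplots(figsize=figsize or (7, 0.6 * len(data) + 1.5))
    _draw_rows(ax, data, band_color)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return data
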