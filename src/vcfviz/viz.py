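"""The four plot types: genotype heatmap, read-depth heatmap, and the two
average-depth scatter plots.

Genotype heatmaps use a discrete four-level scale sampled evenly from
Viridis (colorblind-safe and grayscale-convertible) keyed to the stable
category codes 0-3, so the legend is identical across datasets regardless
of which classes occur.  Depth heatmaps use a monochrome blue ramp with low
depth light and high depth dark — batch effects and poorly covered regions
read as light streaks — and missing cells in a neutral gray outside the
ramp.  Rows are drawn in filtered-record (file) order, top row first; y
axes carry chrom:pos labels and x axes sample IDs.  Optional binary-trait
color bars sit above the heatmap, one strip per trait.

Static export (PDF/SVG/PNG/EPS) is rendered with matplotlib; HTML export is
a self-contained HTML5 document with an inline SVG (every cell carries a
hover label with chromosome position, sample ID and value; pan/zoom via a
small embedded script) viewable in any browser with nothing installed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyResultError, OutputError, UsageError
from .matrices import (MISSING_SENTINEL, DepthMatrix, GenotypeCategory,
                       GenotypeMatrix, SampleMetadata, group_by_trait)

logger = logging.getLogger(__name__)

ALLOWED_FORMATS = ("html", "pdf", "svg", "png", "eps")

#: Four evenly spaced Viridis samples in category-code order 0..3.
CATEGORY_COLORS = ("#440154", "#31688e", "#35b779", "#fde725")
CATEGORY_NAMES = tuple(GenotypeCategory(c).display_name for c in range(4))

#: Trait-strip colors for group 1 / group 2 / missing.
TRAIT_COLORS = {1: "#e66101", 2: "#5e3c99", 0: "#cccccc"}

MISSING_CELL_COLOR = "#bdbdbd"  # neutral gray outside the blue ramp
DEPTH_CMAP = "Blues"            # low -> light, high -> dark


@dataclass
class PlotSpec:
    """User-facing presentation options shared by every plot type."""

    title: str = ""
    show_x_labels: bool = True
    show_y_labels: bool = True
    output_format: str = "html"
    group_trait: str | None = None
    annotate_traits: bool = True
    depth_ceiling: int | None = None

    def __post_init__(self) -> None:
        if self.output_format not in ALLOWED_FORMATS:
            raise UsageError(
                f"unsupported output format {self.output_format!r}; "
                f"choose from {', '.join(ALLOWED_FORMATS)}")
        if self.depth_ceiling is not None and self.depth_ceiling <= 0:
            raise UsageError("depth ceiling must be a positive integer")


@dataclass
class RenderedPlot:
    """Backend-neutral figure description.

    ``values`` keeps the source matrix verbatim (no silent drop: trace
    dimensions always equal matrix dimensions); ``hover`` is a parallel
    grid/list of hover-label strings.
    """

    kind: str                       # genotype_heatmap | depth_heatmap | *_scatter
    title: str
    spec: PlotSpec
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)
    values: np.ndarray | None = None
    hover: list = field(default_factory=list)
    meta: SampleMetadata | None = None       # annotation strips, aligned to cols
    points: list[tuple[str, float]] = field(default_factory=list)  # scatters
    x_title: str = ""
    y_title: str = ""

    # -- static rendering -------------------------------------------------
    def to_matplotlib(self):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        if self.kind.endswith("heatmap"):
            nrows, ncols = self.values.shape
            strips = self.meta.trait_names if (self.meta is not None
                                               and self.spec.annotate_traits) else []
            n_strips = len(strips)
            fig_h = max(3.0, min(0.18 * nrows + 1.5 + 0.3 * n_strips, 40))
            fig_w = max(4.0, min(0.25 * ncols + 2.0, 40))
            fig = plt.figure(figsize=(fig_w, fig_h))
            heights = [0.4] * n_strips + [max(nrows * 0.5, 4)]
            gs = fig.add_gridspec(n_strips + 1, 1, height_ratios=heights,
                                  hspace=0.08)
            for s, trait in enumerate(strips):
                ax_s = fig.add_subplot(gs[s, 0])
                tvals = self.meta.trait_values(trait)
                colors = [TRAIT_COLORS[int(v)] for v in tvals]
                ax_s.bar(np.arange(ncols), np.ones(ncols), width=1.0,
                         color=colors, align="edge")
                ax_s.set_xlim(0, ncols)
                ax_s.set_yticks([])
                ax_s.set_xticks([])
                ax_s.set_ylabel(trait, rotation=0, ha="right", va="center",
                                fontsize=8)
            ax = fig.add_subplot(gs[n_strips, 0])
            if self.kind == "genotype_heatmap":
                cmap = ListedColormap(CATEGORY_COLORS)
                norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5, 3.5], 4)
                im = ax.imshow(self.values, aspect="auto", cmap=cmap, norm=norm,
                               interpolation="nearest")
                cbar = fig.colorbar(im, ax=ax, ticks=[0, 1, 2, 3], shrink=0.8)
                cbar.ax.set_yticklabels(CATEGORY_NAMES, fontsize=8)
            else:
                disp = np.array(self.values, dtype=float)
                vmax = (self.spec.depth_ceiling
                        if self.spec.depth_ceiling is not None
                        else np.nanmax(disp) if np.isfinite(disp).any() else 1.0)
                disp = np.clip(disp, 0, vmax)
                cmap = plt.get_cmap(DEPTH_CMAP).copy()
                cmap.set_bad(MISSING_CELL_COLOR)
                im = ax.imshow(np.ma.masked_invalid(disp), aspect="auto",
                               cmap=cmap, vmin=0, vmax=vmax,
                               interpolation="nearest")
                fig.colorbar(im, ax=ax, shrink=0.8, label="read depth")
            if self.spec.show_x_labels and ncols <= 200:
                ax.set_xticks(np.arange(ncols))
                ax.set_xticklabels(self.col_labels, rotation=90, fontsize=7)
            else:
                ax.set_xticks([])
            if self.spec.show_y_labels and nrows <= 400:
                ax.set_yticks(np.arange(nrows))
                ax.set_yticklabels(self.row_labels, fontsize=7)
            else:
                ax.set_yticks([])
            ax.set_xlabel(self.x_title)
            ax.set_ylabel(self.y_title)
            fig.suptitle(self.title)
            return fig

        # scatter
        labels = [lab for lab, _ in self.points]
        means = [m for _, m in self.points]
        fig, ax = plt.subplots(figsize=(max(4.0, min(0.25 * len(labels) + 2, 40)), 4.5))
        ax.scatter(np.arange(len(means)), means, s=18, color="#31688e")
        if self.spec.show_x_labels and len(labels) <= 200:
            ax.set_xticks(np.arange(len(labels)))
            ax.set_xticklabels(labels, rotation=90, fontsize=7)
        else:
            ax.set_xticks([])
        ax.set_xlabel(self.x_title)
        ax.set_ylabel(self.y_title)
        ax.set_title(self.title)
        fig.tight_layout()
        return fig

    # -- interactive rendering --------------------------------------------
    def to_html(self) -> str:
        from . import _svghtml
        return _svghtml.render_html(self)


def _grouped(matrix, meta, spec):
    """Apply trait grouping when requested; validate the meta dependency."""
    if spec.group_trait is not None:
        if meta is None:
            raise UsageError(
                f"grouping by trait {spec.group_trait!r} requires sample metadata")
        matrix, meta = group_by_trait(matrix, meta, spec.group_trait)
    return matrix, meta


def _heatmap_hover(m, value_fmt) -> list[list[str]]:
    return [[f"{row} | {col} | {value_fmt(m.values[i, j])}"
             for j, col in enumerate(m.col_labels)]
            for i, row in enumerate(m.row_labels)]


def genotype_heatmap(m: GenotypeMatrix, meta: SampleMetadata | None,
                     spec: PlotSpec) -> RenderedPlot:
    """Categorical heatmap of the four genotype classes."""
    if m.values.size == 0:
        raise EmptyResultError("genotype matrix is empty")
    m, meta = _grouped(m, meta, spec)
    hover = _heatmap_hover(m, lambda v: GenotypeCategory(int(v)).display_name)
    return RenderedPlot(kind="genotype_heatmap",
                        title=spec.title or "Genotype heatmap",
                        spec=spec, row_labels=list(m.row_labels),
                        col_labels=list(m.col_labels), values=m.values,
                        hover=hover, meta=meta if spec.annotate_traits else None,
                        x_title="sample ID", y_title="chromosome position")


def depth_heatmap(m: DepthMatrix, meta: SampleMetadata | None,
                  spec: PlotSpec) -> RenderedPlot:
    """Continuous blue heatmap of read depths; missing cells neutral gray."""
    if m.values.size == 0:
        raise EmptyResultError("depth matrix is empty")
    m, meta = _grouped(m, meta, spec)
    hover = _heatmap_hover(
        m, lambda v: MISSING_SENTINEL if np.isnan(v) else str(int(v)))
    return RenderedPlot(kind="depth_heatmap",
                        title=spec.title or "Read depth heatmap",
                        spec=spec, row_labels=list(m.row_labels),
                        col_labels=list(m.col_labels), values=m.values,
                        hover=hover, meta=meta if spec.annotate_traits else None,
                        x_title="sample ID", y_title="chromosome position")


def depth_scatter(points: list[tuple[str, float]], kind: str,
                  spec: PlotSpec) -> RenderedPlot:
    """Scatter of average read depths, one marker per sample or variant."""
    if kind not in ("sample", "variant"):
        raise UsageError(f"scatter kind must be 'sample' or 'variant', got {kind!r}")
    if not points:
        raise EmptyResultError("no points to plot")
    finite = [(lab, m) for lab, m in points if m is not None and not np.isnan(m)]
    dropped = len(points) - len(finite)
    if dropped:
        logger.warning("omitting %d point(s) with missing mean depth", dropped)
    if not finite:
        raise EmptyResultError("all mean depths are missing; nothing to plot")
    x_title = "sample ID" if kind == "sample" else "chromosome position"
    title = spec.title or f"Average {kind} read depth"
    return RenderedPlot(kind=f"{kind}_scatter", title=title, spec=spec,
                        points=finite,
                        hover=[f"{lab} | mean depth {m:.2f}" for lab, m in finite],
                        x_title=x_title, y_title="average read depth")


_MAGIC = {"pdf": b"%PDF", "png": b"\x89PNG", "eps": b"%!PS"}


def save_plot(p: RenderedPlot, path: str | os.PathLike, format: str | None = None) -> None:
    """Save to HTML (self-contained, interactive) or a static format.

    Writes to a temporary sibling and renames atomically, so a failed
    export never leaves a partial artifact behind.
    """
    fmt = (format or p.spec.output_format).lower()
    if fmt not in ALLOWED_FORMATS:
        raise UsageError(
            f"unsupported output format {fmt!r}; choose from {', '.join(ALLOWED_FORMATS)}")
    tmp = f"{path}.tmp"
    try:
        if fmt == "html":
            with open(tmp, "w", encoding="utf-8") as out:
                out.write(p.to_html())
        else:
            import matplotlib.pyplot as plt
            fig = p.to_matplotlib()
            try:
                fig.savefig(tmp, format=fmt)
            finally:
                plt.close(fig)
        os.replace(tmp, path)
    except OSError as exc:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise OutputError(f"cannot write plot to {path}: {exc}") from exc
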