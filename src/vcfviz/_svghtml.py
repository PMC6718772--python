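"""Self-contained HTML5 backend.

Renders a :class:`~vcfviz.viz.RenderedPlot` as an inline SVG wrapped in a
standalone HTML document: no external scripts or stylesheets, so the file
can be opened in any browser by collaborators with nothing installed.
Every heatmap cell / scatter marker carries an SVG ``<title>`` hover label
(chromosome position, sample ID, value), and a small embedded script
provides wheel-zoom and drag-pan over the SVG viewBox.  All row and column
labels are embedded verbatim as text.
"""

from __future__ import annotations

from html import escape

import numpy as np

CELL = 16          # px per heatmap cell
STRIP_H = 14       # px per trait color bar
LEFT = 110         # room for row labels
TOP = 46           # room for title
LABEL_H = 90       # room for rotated column labels
LEGEND_W = 190

_PAN_ZOOM_JS = """
(function () {
  var svg = document.getElementById('plot');
  var vb = svg.viewBox.baseVal;
  var drag = null;
  svg.addEventListener('wheel', function (e) {
    e.preventDefault();
    var k = e.deltaY < 0 ? 0.85 : 1 / 0.85;
    var mx = vb.x + (e.offsetX / svg.clientWidth) * vb.width;
    var my = vb.y + (e.offsetY / svg.clientHeight) * vb.height;
    vb.x = mx - (mx - vb.x) * k; vb.y = my - (my - vb.y) * k;
    vb.width *= k; vb.height *= k;
  }, { passive: false });
  svg.addEventListener('mousedown', function (e) { drag = [e.clientX, e.clientY]; });
  window.addEventListener('mouseup', function () { drag = null; });
  window.addEventListener('mousemove', function (e) {
    if (!drag) return;
    vb.x -= (e.clientX - drag[0]) * vb.width / svg.clientWidth;
    vb.y -= (e.clientY - drag[1]) * vb.height / svg.clientHeight;
    drag = [e.clientX, e.clientY];
  });
})();
"""


def _depth_color(v: float, vmax: float) -> str:
    """Blue ramp, low -> light, high -> dark; matches the static backend."""
    from matplotlib import colormaps
    from matplotlib.colors import to_hex
    frac = 0.0 if vmax <= 0 else min(max(v / vmax, 0.0), 1.0)
    return to_hex(colormaps["Blues"](frac))


def _rect(x, y, w, h, fill, title=None, stroke="none") -> str:
    t = f"<title>{escape(title)}</title>" if title else ""
    return (f'<rect x="{x:.1f}" y="{y:.1f}" width="{w:.1f}" height="{h:.1f}" '
            f'fill="{fill}" stroke="{stroke}">{t}</rect>')


def _text(x, y, s, size=10, anchor="start", rotate=None) -> str:
    tr = f' transform="rotate(-90 {x:.1f} {y:.1f})"' if rotate else ""
    return (f'<text x="{x:.1f}" y="{y:.1f}" font-size="{size}" '
            f'font-family="sans-serif" text-anchor="{anchor}"{tr}>'
            f"{escape(s)}</text>")


def _heatmap_svg(p) -> str:
    from .viz import (CATEGORY_COLORS, CATEGORY_NAMES, MISSING_CELL_COLOR,
                      TRAIT_COLORS)

    nrows, ncols = p.values.shape
    strips = p.meta.trait_names if p.meta is not None else []
    strips_h = len(strips) * (STRIP_H + 2)
    width = LEFT + ncols * CELL + LEGEND_W
    height = TOP + strips_h + nrows * CELL + LABEL_H
    parts: list[str] = []
    parts.append(_text(LEFT, 24, p.title, size=15))

    y0 = TOP
    for s, trait in enumerate(strips):
        tvals = p.meta.trait_values(trait)
        yy = y0 + s * (STRIP_H + 2)
        parts.append(_text(LEFT - 6, yy + STRIP_H - 3, trait, size=9, anchor="end"))
        for j in range(ncols):
            parts.append(_rect(LEFT + j * CELL, yy, CELL, STRIP_H,
                               TRAIT_COLORS[int(tvals[j])],
                               title=f"{trait} | {p.col_labels[j]} | "
                                     f"{int(tvals[j]) or '--'}"))
    y0 += strips_h

    is_geno = p.kind == "genotype_heatmap"
    if not is_geno:
        finite = p.values[np.isfinite(p.values)]
        vmax = (p.spec.depth_ceiling if p.spec.depth_ceiling is not None
                else (float(finite.max()) if finite.size else 1.0))
    for i in range(nrows):
        for j in range(ncols):
            v = p.values[i, j]
            if is_geno:
                fill = CATEGORY_COLORS[int(v)]
            elif np.isnan(v):
                fill = MISSING_CELL_COLOR
            else:
                fill = _depth_color(min(float(v), vmax), vmax)
            parts.append(_rect(LEFT + j * CELL, y0 + i * CELL, CELL, CELL,
                               fill, title=p.hover[i][j]))
    # row labels (always embedded as text for searchability)
    if p.spec.show_y_labels:
        for i, lab in enumerate(p.row_labels):
            parts.append(_text(LEFT - 6, y0 + i * CELL + CELL - 4, lab,
                               size=9, anchor="end"))
    if p.spec.show_x_labels:
        for j, lab in enumerate(p.col_labels):
            parts.append(_text(LEFT + j * CELL + CELL / 2 + 3,
                               y0 + nrows * CELL + 8, lab, size=9,
                               anchor="end", rotate=True))
    # legend
    lx = LEFT + ncols * CELL + 30
    if is_geno:
        for c in range(4):
            parts.append(_rect(lx, y0 + c * 22, 14, 14, CATEGORY_COLORS[c]))
            parts.append(_text(lx + 20, y0 + c * 22 + 11, CATEGORY_NAMES[c], size=10))
    else:
        for k in range(8):
            parts.append(_rect(lx, y0 + k * 14, 14, 14,
                               _depth_color(vmax * (7 - k) / 7, vmax)))
        parts.append(_text(lx + 20, y0 + 11, f"{vmax:g}", size=9))
        parts.append(_text(lx + 20, y0 + 8 * 14, "0", size=9))
        parts.append(_rect(lx, y0 + 9 * 14, 14, 14, MISSING_CELL_COLOR))
        parts.append(_text(lx + 20, y0 + 9 * 14 + 11, "missing (--)", size=9))
    body = "".join(parts)
    return (f'<svg id="plot" xmlns="http://www.w3.org/2000/svg" '
            f'viewBox="0 0 {width} {height}" width="{min(width, 1400)}">{body}</svg>')


def _scatter_svg(p) -> str:
    n = len(p.points)
    means = [m for _, m in p.points]
    plot_w = max(n * 14, 300)
    plot_h = 320
    width = LEFT + plot_w + 40
    height = TOP + plot_h + LABEL_H
    lo, hi = min(means), max(means)
    span = (hi - lo) or 1.0

    def sy(v):  # value -> y px (higher depth up)
        return TOP + plot_h - (v - lo) / span * (plot_h - 40) - 20

    parts = [_text(LEFT, 24, p.title, size=15)]
    parts.append(f'<line x1="{LEFT}" y1="{TOP}" x2="{LEFT}" y2="{TOP + plot_h}" '
                 'stroke="#444"/>')
    parts.append(f'<line x1="{LEFT}" y1="{TOP + plot_h}" x2="{LEFT + plot_w}" '
                 f'y2="{TOP + plot_h}" stroke="#444"/>')
    for tick in (lo, (lo + hi) / 2, hi):
        parts.append(_text(LEFT - 8, sy(tick) + 4, f"{tick:.1f}", size=9, anchor="end"))
    parts.append(_text(18, TOP + plot_h / 2, p.y_title, size=11, anchor="middle",
                       rotate=True))
    step = plot_w / max(n, 1)
    for k, ((lab, m), hov) in enumerate(zip(p.points, p.hover)):
        x = LEFT + step * (k + 0.5)
        parts.append(f'<circle cx="{x:.1f}" cy="{sy(m):.1f}" r="4" '
                     f'fill="#31688e"><title>{escape(hov)}</title></circle>')
        if p.spec.show_x_labels:
            parts.append(_text(x + 3, TOP + plot_h + 10, lab, size=9,
                               anchor="end", rotate=True))
    body = "".join(parts)
    return (f'<svg id="plot" xmlns="http://www.w3.org/2000/svg" '
            f'viewBox="0 0 {width} {height}" width="{min(width, 1400)}">{body}</svg>')


def render_html(p) -> str:
    svg = _heatmap_svg(p) if p.kind.endswith("heatmap") else _scatter_svg(p)
    return f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{escape(p.title)}</title>
<style>body{{margin:16px;font-family:sans-serif}}svg{{cursor:grab}}</style>
</head>
<body>
{svg}
<p>Scroll to zoom, drag to pan; hover a cell for its label.</p>
<script>{_PAN_ZOOM_JS}</script>
</body>
</html>
"""
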