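"""Polygon-based cluster selection on the 2-D embedding, and plot export.

The headless counterpart of drawing a polygon around a cluster in a
scatter plot: membership uses the even-odd (ray casting) rule, with
points exactly on an edge counted as inside, so a drawn boundary captures
the points under it. Visual attributes follow the scatter-plot
conventions of signature-based binning: point size tracks ln(length),
opacity tracks ln(coverage + 1), color encodes the label, and a star
shape flags marker-gene-carrying sequences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingResult
from .io_formats import AnnotationRecord

__all__ = [
    "Polygon",
    "VisualAttributes",
    "point_in_polygon",
    "points_in_polygon",
    "select_cluster",
    "compute_visual_attributes",
    "load_polygons",
    "plot_embedding",
]

SIZE_RANGE = (2.0, 12.0)
OPACITY_RANGE = (0.2, 1.0)


@dataclass(frozen=True)
class Polygon:
    """Ordered vertices of an implicitly closed polygon (>= 3, finite).

    Self-intersecting polygons are permitted; the even-odd rule decides
    membership.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        arr = np.asarray(self.vertices, dtype=float)
        if arr.shape[1] != 2 or not np.isfinite(arr).all():
            raise ValueError("polygon vertices must be finite (x, y) pairs")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


def _on_boundary(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    m = len(poly)
    on = np.zeros(len(px), dtype=bool)
    for a in range(m):
        x1, y1 = poly[a]
        x2, y2 = poly[(a + 1) % m]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (px >= min(x1, x2)) & (px <= max(x1, x2))
            & (py >= min(y1, y2)) & (py <= max(y1, y2))
        )
        on |= (cross == 0.0) & within
    return on


def points_in_polygon(points: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Vectorized even-odd membership; boundary points are inside."""
    poly = polygon.array
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    m = len(poly)
    j = m - 1
    for i in range(m):
        xi, yi = poly[i]
        xj, yj = poly[j]
        crosses = (yi > py) != (yj > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (xj - xi) * (py - yi) / (yj - yi) + xi
        inside ^= crosses & (px < x_at)
        j = i
    return inside | _on_boundary(px, py, poly)


def point_in_polygon(point: Sequence[float], polygon: Polygon) -> bool:
    return bool(points_in_polygon(np.asarray(point, dtype=float)[None, :], polygon)[0])


def select_cluster(
    embedding: EmbeddingResult | np.ndarray,
    polygon: Polygon,
    ids: Sequence[str] | None = None,
) -> list[str]:
    """Ids of the embedded points inside the polygon, in embedding row order.

    An empty selection is valid but warned about.
    """
    if isinstance(embedding, EmbeddingResult):
        coords = embedding.coords
        if ids is None:
            ids = embedding.ids
    else:
        coords = np.asarray(embedding, dtype=float)
    if ids is None:
        raise ValueError("no sequence ids attached to the embedding")
    if len(ids) != len(coords):
        raise ValueError("ids and embedding rows are not aligned")
    mask = points_in_polygon(coords, polygon)
    selected = [i for i, keep in zip(ids, mask) if keep]
    if not selected:
        warnings.warn("polygon selected no points", stacklevel=2)
    return selected


@dataclass
class VisualAttributes:
    """Per-point display attributes for the embedding scatter plot."""

    sizes: np.ndarray        # display units, monotone in ln(length)
    opacities: np.ndarray    # in (0, 1], monotone in ln(coverage + 1)
    colors: list[str]        # one hex color per point, from the label
    shapes: list[str]        # "star" iff the sequence carries a marker gene


def _minmax_scale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.full(len(values), lo)
    return lo + (hi - lo) * (values - vmin) / (vmax - vmin)


def compute_visual_attributes(
    annotations: Sequence[AnnotationRecord] | None,
    lengths: Sequence[int],
) -> VisualAttributes:
    """Map lengths/coverage/label/marker flags to size/opacity/color/shape.

    Missing annotation fields fall back to constant attributes. Coverage
    of 0 is handled by the ln(coverage + 1) offset.
    """
    n = len(lengths)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 1).any():
        raise ValueError("lengths must be >= 1")
    sizes = _minmax_scale(np.log(lengths), *SIZE_RANGE)

    opacities = np.full(n, OPACITY_RANGE[1])
    colors = ["#808080"] * n
    shapes = ["circle"] * n
    if annotations is not None:
        if len(annotations) != n:
            raise ValueError("annotations not aligned to lengths")
        coverages = [a.coverage for a in annotations]
        if all(c is not None for c in coverages):
            cov = np.asarray(coverages, dtype=float)
            if (cov < 0).any():
                raise ValueError("coverage must be >= 0")
            opacities = _minmax_scale(np.log(cov + 1.0), *OPACITY_RANGE)
        labels = [a.label for a in annotations]
        if any(l is not None for l in labels):
            import matplotlib

            palette = [matplotlib.colors.to_hex(c) for c in matplotlib.cm.tab20.colors]
            uniq = sorted({l for l in labels if l is not None})
            lut = {l: palette[i % len(palette)] for i, l in enumerate(uniq)}
            colors = [lut.get(l, "#808080") for l in labels]
        shapes = ["star" if a.is_marker else "circle" for a in annotations]
    return VisualAttributes(sizes=sizes, opacities=opacities, colors=colors, shapes=shapes)


def load_polygons(path: str | Path) -> dict[str, Polygon]:
    """Load named polygons from JSON ({name: [[x, y], ...]}) or CSV (name,x,y)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        raw = json.loads(text)
        return {name: Polygon(tuple(map(tuple, verts))) for name, verts in raw.items()}
    df = pd.read_csv(path, dtype={"name": str, "x": float, "y": float})
    if list(df.columns) != ["name", "x", "y"]:
        raise ValueError("polygon CSV must have columns name,x,y")
    out: dict[str, Polygon] = {}
    for name, grp in df.groupby("name", sort=False):
        out[str(name)] = Polygon(tuple(zip(grp["x"], grp["y"])))
    return out


def plot_embedding(
    embedding: EmbeddingResult | np.ndarray,
    path: str | Path,
    attributes: VisualAttributes | None = None,
    polygons: dict[str, Polygon] | None = None,
) -> None:
    """Export a static scatter plot of the embedding (PNG/PDF/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coords if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    fig, ax = plt.subplots(figsize=(7, 7))
    if attributes is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=9, c="#404040", alpha=0.7, linewidths=0)
    else:
        shapes = np.asarray(attributes.shapes)
        for marker, shape in (("o", "circle"), ("*", "star")):
            sel = shapes == shape
            if not sel.any():
                continue
            rgba = [
                matplotlib.colors.to_rgba(c, alpha=a)
                for c, a in zip(
                    np.asarray(attributes.colors, dtype=object)[sel],
                    attributes.opacities[sel],
                )
            ]
            ax.scatter(
                coords[sel, 0],
                coords[sel, 1],
                s=attributes.sizes[sel] ** 2,
                c=rgba,
                marker=marker,
                linewidths=0,
            )
    if polygons:
        for name, poly in polygons.items():
            arr = np.vstack([poly.array, poly.array[:1]])
            ax.plot(arr[:, 0], arr[:, 1], "r-", lw=1)
            ax.annotate(name, poly.array.mean(axis=0), color="red", fontsize=8)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
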