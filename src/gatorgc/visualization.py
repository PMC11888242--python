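"""Vector figures: conservation diagrams, focal neighborhoods, clustered heatmap.

All figures are SVG (optionally PDF) and are pure functions of their
inputs. Gene glyphs and homology rails carry stable SVG group ids
(``gene__*``, ``rail__*``, ``cell__*``) so figure content is testable by
parsing the XML.

Color semantics: required-query genes purple, optional-query genes
orange, all other genes green; genes at a contig edge get a red outline.
Fill opacity encodes per-gene conservation (0 = absent from every other
window = fully transparent, 1 = universally conserved = fully opaque).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Polygon, Rectangle
from scipy.cluster import hierarchy

from .diversity import ClusterOrder
from .homology import HomologyHit
from .scoring import GfsMatrix, PresenceAbsence
from .windows import GatorWindow

COLOR_REQUIRED = "#800080"  # purple
COLOR_OPTIONAL = "#FFA500"  # orange
COLOR_OTHER = "#008000"     # green
COLOR_EDGE = "#FF0000"      # red outline for contig-edge genes

_SAVE_KW = {"format": "svg", "metadata": {"Date": None}}


def _save(fig, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with plt.rc_context({"svg.hashsalt": "gatorgc"}):
        fig.savefig(out_path, **_SAVE_KW)
    plt.close(fig)
    return out_path


@dataclass
class ConservationProfile:
    window_id: str
    fractions: dict[str, float]  # gene_id -> share of windows carrying it

    def values(self, window: GatorWindow) -> list[float]:
        return [self.fractions[g.gene_id] for g in window.genes]


def conservation_profile(focal: GatorWindow, presence: PresenceAbsence) -> ConservationProfile:
    """Per-gene conservation = windows carrying the gene / all windows.

    Computed over the rows of the focal presence-absence table (the focal
    row included), typically the deduplicated window set.
    """
    matrix = presence.matrix
    fractions = (matrix.sum(axis=0) / len(matrix)).to_dict()
    return ConservationProfile(focal.window_id, {g: float(v) for g, v in fractions.items()})


def _gene_color(window: GatorWindow, gene_id: str) -> str:
    assignment = window.hit_assignments.get(gene_id)
    if assignment is None:
        return COLOR_OTHER
    return COLOR_REQUIRED if assignment.role == "required" else COLOR_OPTIONAL


def _arrow(x1: float, x2: float, y: float, height: float, strand: int) -> list[tuple[float, float]]:
    head = min(0.3 * (x2 - x1), height * 1.5)
    y0, y1 = y - height / 2, y + height / 2
    if strand >= 0:
        return [(x1, y0), (x2 - head, y0), (x2, y), (x2 - head, y1), (x1, y1)]
    return [(x2, y0), (x1 + head, y0), (x1, y), (x1 + head, y1), (x2, y1)]


def _draw_track(ax, window: GatorWindow, y: float, opacities: Sequence[float] | None,
                gid_prefix: str, height: float = 0.5,
                label_queries: bool = True) -> None:
    offset = window.span_start
    for i, gene in enumerate(window.genes):
        x1, x2 = gene.start - offset, gene.end - offset
        color = _gene_color(window, gene.gene_id)
        edge = COLOR_EDGE if gene.contig_edge else "#000000"
        patch = Polygon(_arrow(x1, x2, y, height, gene.strand), closed=True,
                        facecolor=color, edgecolor=edge, linewidth=1.2)
        patch.set_alpha(opacities[i] if opacities is not None else 1.0)
        patch.set_gid(f"{gid_prefix}__{i}")
        ax.add_patch(patch)
        assignment = window.hit_assignments.get(gene.gene_id)
        if label_queries and assignment is not None:
            ax.text((x1 + x2) / 2, y + height * 0.75, assignment.query_id,
                    ha="center", va="bottom", fontsize=7, rotation=30)


def _scale_bar(ax, length: int, y: float) -> None:
    bar = 10 ** int(np.floor(np.log10(max(length, 10)))) / 2
    ax.plot([0, bar], [y, y], color="black", linewidth=2)
    ax.text(bar / 2, y - 0.18, f"{bar / 1000:g} kb", ha="center", va="top", fontsize=7)


def draw_conservation(window: GatorWindow, profile: ConservationProfile,
                      out_path: str | Path) -> Path:
    """One window as a gene-arrow track, fill opacity = conservation."""
    fig, ax = plt.subplots(figsize=(max(6.0, window.length_bp / 8000), 2.2))
    _draw_track(ax, window, y=1.0, opacities=profile.values(window), gid_prefix="gene")
    ax.text(0, 1.85, f"{window.window_id}  ({window.length_bp / 1000:.1f} kb)",
            fontsize=9, ha="left")
    _scale_bar(ax, window.length_bp, y=0.25)
    ax.set_xlim(-window.length_bp * 0.02, window.length_bp * 1.02)
    ax.set_ylim(0, 2.2)
    ax.axis("off")
    return _save(fig, out_path)


def _rail_endpoints(window: GatorWindow, gene_idx: Mapping[str, int],
                    gene_id: str, aa_start: int, aa_end: int) -> tuple[float, float]:
    gene = window.genes[gene_idx[gene_id]]
    offset = window.span_start
    aa_len = max(1, len(gene.protein_seq))
    aa_start = min(max(1, aa_start), aa_len)
    aa_end = min(max(aa_start, aa_end), aa_len)
    if gene.strand >= 0:
        return (gene.start - offset + 3 * (aa_start - 1),
                gene.start - offset + 3 * aa_end)
    return (gene.end - offset - 3 * aa_end,
            gene.end - offset - 3 * (aa_start - 1))


def draw_neighborhood(focal: GatorWindow, windows: Sequence[GatorWindow],
                      gfs_column: Mapping[str, float],
                      hits: Iterable[HomologyHit],
                      out_path: str | Path) -> Path:
    """Focal window on top, the rest below in descending score order.

    Query annotations appear only on the focal track. Homology rails run
    between consecutive tracks from the alignment coordinates; for a
    modular gene only its best-bit-score hit is railed, for non-modular
    genes all passing hits are.
    """
    others = sorted((w for w in windows if w.window_id != focal.window_id),
                    key=lambda w: (-gfs_column.get(w.window_id, 0.0), w.window_id))
    tracks = [focal] + others
    n = len(tracks)
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query_id, []).append(h)

    fig, ax = plt.subplots(figsize=(max(6.0, max(t.length_bp for t in tracks) / 8000),
                                    1.2 + 1.1 * n))
    max_len = max(t.length_bp for t in tracks)
    for row, track in enumerate(tracks):
        y = (n - row) * 1.1
        _draw_track(ax, track, y=y, opacities=None, gid_prefix=f"track{row}_gene",
                    label_queries=(row == 0))
        score = 1.0 if row == 0 else gfs_column.get(track.window_id, 0.0)
        ax.text(max_len * 1.01, y, f"{track.window_id}  GFS={score:.3f}",
                fontsize=7, va="center")
    for row in range(n - 1):
        upper, lower = tracks[row], tracks[row + 1]
        upper_idx = {g.gene_id: i for i, g in enumerate(upper.genes)}
        lower_idx = {g.gene_id: i for i, g in enumerate(lower.genes)}
        y_hi = (n - row) * 1.1 - 0.28
        y_lo = (n - row - 1) * 1.1 + 0.28
        for gene in upper.genes:
            pair_hits = [h for h in hits_by_query.get(gene.gene_id, [])
                         if h.subject_id in lower_idx]
            if not pair_hits:
                continue
            category = upper.categories.get(gene.gene_id)
            if category is not None and category.is_modular:
                pair_hits = [max(pair_hits, key=lambda h: h.bit_score)]
            for h in pair_hits:
                qx1, qx2 = _rail_endpoints(upper, upper_idx, h.query_id,
                                           h.q_start, h.q_end)
                sx1, sx2 = _rail_endpoints(lower, lower_idx, h.subject_id,
                                           h.s_start, h.s_end)
                rail = Polygon([(qx1, y_hi), (qx2, y_hi), (sx2, y_lo), (sx1, y_lo)],
                               closed=True, facecolor="#808080",
                               edgecolor="none")
                rail.set_alpha(0.25 + 0.55 * h.pct_identity / 100.0)
                rail.set_gid(f"rail__{row}__{h.query_id}__{h.subject_id}")
                ax.add_patch(rail)
    _scale_bar(ax, max_len, y=0.3)
    ax.set_xlim(-max_len * 0.02, max_len * 1.35)
    ax.set_ylim(0, (n + 1) * 1.1 + 0.6)
    ax.axis("off")
    return _save(fig, out_path)


def draw_heatmap(matrix: GfsMatrix, order: ClusterOrder,
                 out_path: str | Path, cmap: str = "viridis") -> Path:
    """Clustered score heatmap with its dendrogram, rows/cols in leaf order.

    Cells are individual vector rectangles (gid ``cell__i__j``); the color
    scale is linear on [0, 1].
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    ordered = values.loc[order.leaves, order.leaves]
    n = len(order.leaves)
    colormap = plt.get_cmap(cmap)
    fig = plt.figure(figsize=(max(4.0, 0.5 * n + 2.5), max(3.2, 0.5 * n + 1.5)))
    if order.linkage.size:
        ax_d = fig.add_axes([0.02, 0.25, 0.18, 0.65])
        hierarchy.dendrogram(order.linkage, orientation="left", no_labels=True,
                             ax=ax_d, link_color_func=lambda _: "#404040")
        ax_d.invert_yaxis()
        ax_d.axis("off")
    ax = fig.add_axes([0.25, 0.25, 0.62, 0.65])
    data = ordered.to_numpy(dtype=float)
    for i in range(n):
        for j in range(n):
            cell = Rectangle((j, n - 1 - i), 1, 1,
                             facecolor=colormap(np.clip(data[i, j], 0.0, 1.0)),
                             edgecolor="none")
            cell.set_gid(f"cell__{i}__{j}")
            ax.add_patch(cell)
    ax.set_xlim(0, n)
    ax.set_ylim(0, n)
    ax.set_xticks(np.arange(n) + 0.5)
    ax.set_xticklabels(order.leaves, rotation=90, fontsize=6)
    ax.set_yticks(np.arange(n) + 0.5)
    ax.set_yticklabels(reversed(order.leaves), fontsize=6)
    sm = plt.cm.ScalarMappable(cmap=colormap, norm=plt.Normalize(0.0, 1.0))
    fig.colorbar(sm, ax=ax, fraction=0.04, label="GFS")
    return _save(fig, out_path)
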