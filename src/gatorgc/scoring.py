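"""Proximity-weighted window similarity (GATOR Focal Score) and deduplication.

Every gene of a focal window gets a weight from a decaying Gaussian
centred on the query-assigned (anchor) genes: weight 1 at each anchor,
``exp(-d^2 / (2 sigma^2))`` at ordinal distance d, the maximum taken over
anchors. The focal score of a target window is the weighted fraction of
focal genes present in the target, so it lives in [0, 1], with 1 meaning
the target carries every focal gene (weighted emphasis near the queries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import HomologyHit
from .windows import GatorWindow

logger = logging.getLogger(__name__)

#: Tolerance for treating a score as exactly 1.0 during deduplication
#: (absorbs float summation order).
DEDUP_TOL = 1e-9


def default_sigma(n_genes: int) -> float:
    """Index-space Gaussian width: max(1, n_genes / 6).

    An anchor at one window edge then decays to ~e^-18 at the far edge,
    i.e. effectively zero, while neighbours within a few genes keep
    substantial weight.
    """
    return max(1.0, n_genes / 6.0)


@dataclass
class WeightVector:
    window_id: str
    weights: np.ndarray  # per focal gene, ordered as window.genes
    anchor_indices: list[int] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def compute_weights(window: GatorWindow, sigma: float | None = None,
                    mode: str = "index") -> WeightVector:
    """Per-gene anchor-proximity weights for a focal window.

    mode="index" measures distance in gene ordinals (default; invariant to
    intergenic-length noise); mode="bp" measures distance between gene
    midpoints in bp, with ``sigma`` then in bp.
    """
    anchors = window.anchor_indices()
    if not anchors:
        raise ValueError(f"window {window.window_id} has no query-assigned genes")
    n = len(window.genes)
    if mode == "index":
        positions = np.arange(n, dtype=float)
        anchor_pos = np.array(anchors, dtype=float)
        s = default_sigma(n) if sigma is None else float(sigma)
    elif mode == "bp":
        positions = np.array([(g.start + g.end) / 2.0 for g in window.genes])
        anchor_pos = positions[anchors]
        if sigma is None:
            raise ValueError("bp mode requires an explicit sigma (in bp)")
        s = float(sigma)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    if s <= 0:
        raise ValueError("sigma must be positive")
    d = positions[:, None] - anchor_pos[None, :]
    weights = np.exp(-(d ** 2) / (2.0 * s * s)).max(axis=1)
    weights[anchors] = 1.0  # exact amplitude at anchors
    return WeightVector(window.window_id, weights, list(anchors))


@dataclass
class PresenceAbsence:
    focal_id: str
    matrix: pd.DataFrame  # rows = target window ids, columns = focal gene ids

    def row(self, window_id: str) -> np.ndarray:
        return self.matrix.loc[window_id].to_numpy(dtype=bool)


def _subject_lookup(hits: Iterable[HomologyHit]) -> dict[str, set[str]]:
    lookup: dict[str, set[str]] = {}
    for h in hits:
        lookup.setdefault(h.query_id, set()).add(h.subject_id)
    return lookup


def presence_absence(focal: GatorWindow, targets: Sequence[GatorWindow],
                     search, min_qcov: float | None = None,
                     min_pid: float | None = None) -> PresenceAbsence:
    """Gene-level presence of each focal gene in every target window.

    ``search`` is either a pre-computed list of HomologyHits (queries =
    focal gene ids, subjects = target gene ids) or an engine with a
    ``search(queries, db)`` method. Cell (t, g) is True iff focal gene g
    has at least one passing hit to any protein of window t.
    """
    if hasattr(search, "search"):
        db = [p for t in targets for p in t.proteins()]
        if min_qcov is not None:
            search.min_qcov = min_qcov
        if min_pid is not None:
            search.min_pid = min_pid
        hits = search.search(focal.proteins(), db)
    else:
        hits = list(search)
    lookup = _subject_lookup(hits)
    gene_ids = focal.gene_ids
    data = {}
    for target in targets:
        target_genes = set(target.gene_ids)
        data[target.window_id] = [bool(lookup.get(g, set()) & target_genes)
                                  for g in gene_ids]
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=gene_ids)
    matrix = matrix.loc[sorted(data)]
    return PresenceAbsence(focal.window_id, matrix)


def gfs(weights: WeightVector, presence_row: Sequence[bool] | np.ndarray) -> float:
    """Weighted presence ratio: sum(w * present) / sum(w), in [0, 1].

    Each focal gene contributes at most once regardless of how many
    target proteins it hits (presence is boolean per gene).
    """
    row = np.asarray(presence_row, dtype=bool)
    if row.shape != weights.weights.shape:
        raise ValueError("presence row does not align with the weight vector")
    return float(weights.weights[row].sum() / weights.total)


@dataclass
class GfsMatrix:
    """All-vs-all scores: rows = windows, columns = focal windows."""

    values: pd.DataFrame

    @property
    def window_ids(self) -> list[str]:
        return list(self.values.index)


def _global_hits(windows: Sequence[GatorWindow], search) -> list[HomologyHit]:
    proteins = [p for w in windows for p in w.proteins()]
    if hasattr(search, "search"):
        return search.search(proteins, proteins)
    return list(search)


def all_vs_all(windows: Sequence[GatorWindow], search,
               sigma: float | None = None,
               precomputed: Mapping[str, PresenceAbsence] | None = None
               ) -> tuple[GfsMatrix, dict[str, PresenceAbsence]]:
    """Score every window against every focal window.

    Returns the score matrix (column j = scores of all windows against
    focal j) and the per-focal presence-absence tables it was derived
    from. One homology search over the pooled window proteins backs all
    tables.
    """
    if len(windows) == 0:
        raise ValueError("no windows to score")
    windows = sorted(windows, key=lambda w: w.window_id)
    ids = [w.window_id for w in windows]
    if precomputed is None:
        hits = _global_hits(windows, search)
        tables = {w.window_id: presence_absence(w, windows, hits) for w in windows}
    else:
        tables = dict(precomputed)
    values = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for focal in windows:
        wv = compute_weights(focal, sigma=sigma)
        table = tables[focal.window_id]
        for wid in ids:
            values.loc[wid, focal.window_id] = gfs(wv, table.row(wid))
    return GfsMatrix(values), tables


@dataclass
class DeduplicationMap:
    """rep window id -> removed window ids; focal processing order."""

    representatives: dict[str, list[str]] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)

    @property
    def removed(self) -> set[str]:
        return {wid for removed in self.representatives.values() for wid in removed}


def deduplicate(windows: Sequence[GatorWindow], search,
                tol: float = DEDUP_TOL, mutual: bool = False,
                sigma: float | None = None,
                precomputed: Mapping[str, PresenceAbsence] | None = None
                ) -> tuple[list[GatorWindow], DeduplicationMap]:
    """Remove windows identical to a focal window (score 1.0).

    Focal windows are processed by genomic length descending (ties by
    window id); any not-yet-processed window scoring >= 1 - tol against
    the current focal is removed and mapped to it. Windows that already
    served as focal are final representatives and cannot be removed by a
    later (shorter) focal — otherwise a window whose gene content is a
    strict subset of a longer one would score 1.0 one-directionally and
    evict it. ``mutual=True`` additionally requires the score to be 1 in
    both directions before removal. Presence of a focal gene in a target
    is independent of other windows, so tables computed once remain
    exact as windows leave the pool.
    """
    if not windows:
        return [], DeduplicationMap()
    by_id = {w.window_id: w for w in windows}
    if precomputed is None:
        hits = _global_hits(sorted(windows, key=lambda w: w.window_id), search)
        tables = {w.window_id: presence_absence(w, list(windows), hits)
                  for w in windows}
    else:
        tables = dict(precomputed)
    weights = {w.window_id: compute_weights(w, sigma=sigma) for w in windows}

    def score(focal_id: str, target_id: str) -> float:
        return gfs(weights[focal_id], tables[focal_id].row(target_id))

    order = sorted(by_id, key=lambda wid: (-by_id[wid].length_bp, wid))
    removed: set[str] = set()
    dedup = DeduplicationMap()
    for i, focal_id in enumerate(order):
        if focal_id in removed:
            continue
        dedup.order.append(focal_id)
        dedup.representatives[focal_id] = []
        for target_id in order[i + 1:]:
            if target_id in removed:
                continue
            identical = score(focal_id, target_id) >= 1.0 - tol
            if identical and mutual:
                identical = score(target_id, focal_id) >= 1.0 - tol
            if identical:
                removed.add(target_id)
                dedup.representatives[focal_id].append(target_id)
    unique = [by_id[wid] for wid in sorted(by_id) if wid not in removed]
    return unique, dedup


def export_scores(matrix: GfsMatrix, tables: Mapping[str, PresenceAbsence],
                  dedup: DeduplicationMap | None, out_dir) -> None:
    """Write the CSV trees: per-focal presence/score tables, the
    concatenated matrix and the deduplication log."""
    from pathlib import Path

    out_dir = Path(out_dir)
    pa_dir = out_dir / "presence_absence"
    gs_dir = out_dir / "gator_scores"
    cc_dir = out_dir / "concatenated_scores"
    for d in (pa_dir, gs_dir, cc_dir):
        d.mkdir(parents=True, exist_ok=True)
    for focal_id in sorted(tables):
        safe = _safe(focal_id)
        tables[focal_id].matrix.astype(int).to_csv(pa_dir / f"{safe}.csv",
                                                   index_label="window_id")
        column = matrix.values[focal_id].sort_values(ascending=False)
        column.rename("gfs").to_csv(gs_dir / f"{safe}.csv", index_label="window_id")
    matrix.values.to_csv(cc_dir / "gfs_matrix.csv", index_label="window_id")
    if dedup is not None:
        dd_dir = out_dir / "deduplication_process"
        dd_dir.mkdir(parents=True, exist_ok=True)
        rows = [{"focal_window": fid, "removed_window": rid}
                for fid in dedup.order for rid in dedup.representatives[fid]]
        pd.DataFrame(rows, columns=["focal_window", "removed_window"]).to_csv(
            dd_dir / "deduplication.csv", index=False)


def _safe(window_id: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in window_id)
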