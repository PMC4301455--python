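"""Segmentation scoring against a reference labeled mask.

Pixel-level agreement is scored with the Adjusted Rand Index computed
from the label-overlap contingency table, with background discarded:
the counted pixels T are those foreground in at least one mask, and a
pixel foreground in only one mask enters that mask's cell as usual but
forms a singleton in the other partition (so it can only disagree).
Cell-level detection is scored by mutual-majority matching: a reference
cell is a true positive iff a single test cell covers more than the
overlap fraction of its pixels and the reference cell covers more than
that fraction of the test cell. CCA = TP / (N + FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyTable",
    "SegmentationMetrics",
    "contingency",
    "adjusted_rand_index",
    "match_cells",
    "cell_count_accuracy",
    "evaluate_pair",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Overlap pixel counts between reference cells and test cells.

    ``n_ij[i, j]`` counts pixels shared by reference cell ``ref_ids[i]``
    and test cell ``seg_ids[j]`` (both foreground). ``a`` and ``b`` are
    the full per-cell pixel counts over T — the pixels foreground in at
    least one mask — so ``a.sum()`` and ``b.sum()`` may be smaller than
    ``T`` when a mask leaves part of the union uncovered; those uncovered
    pixels are singletons of the other partition.
    """

    n_ij: np.ndarray
    a: np.ndarray
    b: np.ndarray
    T: int
    ref_ids: np.ndarray
    seg_ids: np.ndarray


def contingency(ref: np.ndarray, seg: np.ndarray) -> ContingencyTable:
    """Exact overlap counts over pixels foreground in at least one mask."""
    ref = np.asarray(ref)
    seg = np.asarray(seg)
    if ref.shape != seg.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {seg.shape}")
    union = (ref > 0) | (seg > 0)
    T = int(union.sum())
    ref_ids = np.unique(ref[ref > 0])
    seg_ids = np.unique(seg[seg > 0])
    ridx = np.zeros(int(ref.max()) + 1 if ref.size else 1, dtype=np.int64)
    ridx[ref_ids] = np.arange(ref_ids.size)
    sidx = np.zeros(int(seg.max()) + 1 if seg.size else 1, dtype=np.int64)
    sidx[seg_ids] = np.arange(seg_ids.size)

    both = (ref > 0) & (seg > 0)
    n_ij = np.zeros((ref_ids.size, seg_ids.size), dtype=np.int64)
    if both.any():
        flat = ridx[ref[both]] * seg_ids.size + sidx[seg[both]]
        counts = np.bincount(flat, minlength=ref_ids.size * seg_ids.size)
        n_ij = counts.reshape(ref_ids.size, seg_ids.size)
    a = np.bincount(ridx[ref[ref > 0]], minlength=ref_ids.size) if ref_ids.size else np.zeros(0, np.int64)
    b = np.bincount(sidx[seg[seg > 0]], minlength=seg_ids.size) if seg_ids.size else np.zeros(0, np.int64)
    return ContingencyTable(
        n_ij=n_ij, a=a.astype(np.int64), b=b.astype(np.int64),
        T=T, ref_ids=ref_ids, seg_ids=seg_ids,
    )


def _comb2(x: np.ndarray | int):
    """C(n, 2) in exact integer arithmetic."""
    x = np.asarray(x, dtype=object)
    return x * (x - 1) // 2


def adjusted_rand_index(ref: np.ndarray, seg: np.ndarray) -> float:
    """Chance-corrected pixel-pair agreement between two labelings.

    Background is discarded: only pixels foreground in at least one mask
    are counted, and pixels foreground in exactly one mask are treated
    as singletons of the other partition. Bounded above by 1 (identical
    partitions); if both partitions are trivial the degenerate 0/0 is
    returned as 1.0 by convention.
    """
    tab = contingency(ref, seg)
    if tab.T == 0:
        raise ValueError("both masks are empty")
    sum_nij = int(np.sum(_comb2(tab.n_ij)))
    sum_a = int(np.sum(_comb2(tab.a)))
    sum_b = int(np.sum(_comb2(tab.b)))
    total = int(_comb2(tab.T))
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        return 1.0  # both partitions trivial: no chance correction possible
    return float((sum_nij - expected) / (maximum - expected))


def match_cells(
    ref: np.ndarray,
    seg: np.ndarray,
    overlap_fraction: float = 0.5,
) -> tuple[int, int, int, int, int]:
    """Majority-overlap cell matching: (TP, FP, FN, over, under).

    With ``f = overlap_fraction``, test cell j "claims" reference cell i
    when their overlap exceeds f of j's pixels, and i "fills" j when the
    overlap exceeds f of i's pixels. TP counts reference cells with a
    mutual claim; over-segmented reference cells are claimed by >= 2 test
    cells; under-segmenting test cells are filled by >= 2 reference
    cells; FP test cells and FN reference cells participate in no claim
    or fill at all.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    tab = contingency(ref, seg)
    n = tab.n_ij.astype(np.float64)
    a = tab.a.astype(np.float64)[:, None]
    b = tab.b.astype(np.float64)[None, :]
    claims = n > overlap_fraction * b   # test j mostly inside ref i
    fills = n > overlap_fraction * a    # ref i mostly inside test j
    tp = int(np.sum(np.any(claims & fills, axis=1)))
    over = int(np.sum(claims.sum(axis=1) >= 2))
    under = int(np.sum(fills.sum(axis=0) >= 2))
    fp = int(np.sum(~np.any(claims | fills, axis=0)))
    fn = int(np.sum(~np.any(claims | fills, axis=1)))
    return tp, fp, fn, over, under


def cell_count_accuracy(tp: int, n_ref: int, fp: int) -> float:
    """CCA = TP / (N + FP)."""
    if n_ref < 1:
        raise ValueError("reference cell count N must be >= 1")
    return tp / (n_ref + fp)


@dataclass(frozen=True)
class SegmentationMetrics:
    """Per-image segmentation scores."""

    N: int
    TP: int
    FP: int
    FN: int
    over_segmented: int
    under_segmented: int
    CCA: float
    ARI: float


def evaluate_pair(
    ref: np.ndarray,
    seg: np.ndarray,
    overlap_fraction: float = 0.5,
) -> SegmentationMetrics:
    """All metrics for one (reference, test) mask pair."""
    ref = np.asarray(ref)
    seg = np.asarray(seg)
    n_ref = int(np.unique(ref[ref > 0]).size)
    tp, fp, fn, over, under = match_cells(ref, seg, overlap_fraction)
    cca = cell_count_accuracy(tp, n_ref, fp) if n_ref >= 1 else 0.0
    ari = adjusted_rand_index(ref, seg)
    return SegmentationMetrics(
        N=n_ref, TP=tp, FP=fp, FN=fn,
        over_segmented=over, under_segmented=under,
        CCA=cca, ARI=ari,
    )
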