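"""Geodesic traversability masks, distances, and nearest-seed assignment.

The geodesic mask is a binary traversability map: boundary pixels (above
a configured intensity percentile inside the ROI, for bright-boundary
modalities) cannot be crossed, so distances between pixels respect cell
boundaries as obstacles. Path length is counted in steps — unit cost per
move, diagonals included under 8-connectivity — with disconnected pixels
at the infinity sentinel. A Dijkstra variant with sqrt(2)-cost diagonals
is available via ``diagonal_cost``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "GeodesicMask",
    "build_geodesic_mask",
    "geodesic_distance",
    "nearest_seed_assignment",
    "geodesic_label_spread",
    "euclidean_label_spread",
]

_OFFSETS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _offsets(connectivity: int) -> list[tuple[int, int]]:
    if connectivity == 8:
        return _OFFSETS_8
    if connectivity == 4:
        return _OFFSETS_4
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass(frozen=True)
class GeodesicMask:
    """Traversability map: True = path pixel, False = impassable boundary.

    ``traversable`` is always a subset of ``roi``; everything outside the
    ROI is non-traversable.
    """

    traversable: np.ndarray
    roi: np.ndarray

    def __post_init__(self) -> None:
        if self.traversable.shape != self.roi.shape:
            raise ValueError("traversable and roi shapes differ")


def build_geodesic_mask(
    img: np.ndarray,
    roi: np.ndarray,
    boundary_percentile: float = 85.0,
    polarity: str = "bright",
) -> GeodesicMask:
    """Mark ROI pixels beyond the boundary percentile as non-traversable.

    For ``polarity='bright'`` a pixel is a boundary iff it lies in the
    ROI and its intensity exceeds the given percentile of the ROI
    intensities (strictly); ``'dark'`` flips the comparison. Percentiles
    use linear interpolation over ROI pixels only.
    """
    img = np.asarray(img, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if img.shape != roi.shape:
        raise ValueError("image and ROI shapes differ")
    if not 0.0 <= boundary_percentile <= 100.0:
        raise ValueError(f"boundary_percentile must be in [0, 100], got {boundary_percentile}")
    if not roi.any():
        raise ValueError("empty ROI")
    p = np.percentile(img[roi], boundary_percentile)
    if polarity == "bright":
        boundary = img > p
    elif polarity == "dark":
        boundary = img < p
    else:
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    return GeodesicMask(traversable=roi & ~boundary, roi=roi)


def _as_traversable(mask: GeodesicMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, GeodesicMask):
        return np.asarray(mask.traversable, dtype=bool)
    return np.asarray(mask, dtype=bool)


def geodesic_label_spread(
    labels: np.ndarray,
    allowed: np.ndarray,
    connectivity: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Spread labels into ``allowed`` pixels by multi-source BFS.

    Returns ``(lab, dist)`` where every reachable allowed pixel carries
    the smallest label among those at minimum step distance, and ``dist``
    holds step counts (np.inf where unreachable). Source pixels
    (``labels > 0``) keep their label at distance 0 regardless of
    ``allowed``; expansion only enters allowed pixels.
    """
    labels = np.asarray(labels)
    allowed = np.asarray(allowed, dtype=bool)
    if labels.shape != allowed.shape:
        raise ValueError("labels and allowed shapes differ")
    h, w = labels.shape
    offs = _offsets(connectivity)

    # padded working copies: the 1-px border is never allowed
    lab = np.zeros((h + 2, w + 2), dtype=np.int64)
    lab[1:-1, 1:-1] = labels
    dist = np.full((h + 2, w + 2), np.inf)
    dist[1:-1, 1:-1][labels > 0] = 0.0
    allow = np.zeros((h + 2, w + 2), dtype=bool)
    allow[1:-1, 1:-1] = allowed

    frontier = np.zeros((h + 2, w + 2), dtype=bool)
    frontier[1:-1, 1:-1] = labels > 0
    open_ = allow & (lab == 0)
    d = 0.0
    sentinel = np.iinfo(np.int64).max
    while frontier.any() and open_.any():
        cand = np.full((h + 2, w + 2), sentinel, dtype=np.int64)
        core_cand = cand[1:-1, 1:-1]
        core_open = open_[1:-1, 1:-1]
        for dr, dc in offs:
            nb_front = frontier[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            nb_lab = lab[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
            sel = core_open & nb_front
            np.minimum(core_cand, np.where(sel, nb_lab, sentinel), out=core_cand)
        newly = cand < sentinel
        if not newly.any():
            break
        d += 1.0
        lab[newly] = cand[newly]
        dist[newly] = d
        frontier = newly
        open_ &= ~newly
    return lab[1:-1, 1:-1], dist[1:-1, 1:-1]


def _dijkstra_spread(
    labels: np.ndarray,
    allowed: np.ndarray,
    connectivity: int,
    diagonal_cost: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Heap-based variant for non-unit diagonal step costs."""
    h, w = labels.shape
    offs = _offsets(connectivity)
    costs = [diagonal_cost if dr != 0 and dc != 0 else 1.0 for dr, dc in offs]
    dist = np.full((h, w), np.inf)
    lab = np.asarray(labels, dtype=np.int64).copy()
    heap: list[tuple[float, int, int, int]] = []
    rs, cs = np.nonzero(labels > 0)
    for r, c in zip(rs.tolist(), cs.tolist()):
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, int(labels[r, c]), r, c))
    src = labels > 0
    while heap:
        d, l, r, c = heapq.heappop(heap)
        if d > dist[r, c] or (d == dist[r, c] and l > lab[r, c]):
            continue  # stale heap entry
        for (dr, dc), step in zip(offs, costs):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w):
                continue
            if src[nr, nc] or not allowed[nr, nc]:
                continue
            nd = d + step
            if nd < dist[nr, nc] or (nd == dist[nr, nc] and l < lab[nr, nc]):
                dist[nr, nc] = nd
                lab[nr, nc] = l
                heapq.heappush(heap, (nd, l, nr, nc))
    return lab, dist


def geodesic_distance(
    mask: GeodesicMask | np.ndarray,
    sources: Iterable[tuple[int, int]],
    connectivity: int = 8,
    diagonal_cost: float = 1.0,
) -> np.ndarray:
    """Shortest-path step distance from a source set over traversable pixels.

    Exact on the pixel adjacency graph restricted to traversable pixels;
    np.inf marks pixels not connected to any source. Unit cost per move
    by default (so with no obstacles and 8-connectivity the result is the
    Chebyshev distance); set ``diagonal_cost=sqrt(2)`` for Euclidean-
    weighted steps.
    """
    trav = _as_traversable(mask)
    sources = list(sources)
    if not sources:
        raise ValueError("empty source set")
    seeds = np.zeros(trav.shape, dtype=np.int64)
    for r, c in sources:
        if not trav[r, c]:
            raise ValueError(f"source pixel {(r, c)} is not traversable")
        seeds[r, c] = 1
    if diagonal_cost == 1.0 or connectivity == 4:
        _, dist = geodesic_label_spread(seeds, trav, connectivity)
    else:
        _, dist = _dijkstra_spread(seeds, trav, connectivity, diagonal_cost)
    return dist


def euclidean_label_spread(
    labels: np.ndarray,
    within: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each ``within`` pixel to the Euclidean-nearest label object.

    Obstacles are ignored. Ties at equal distance go to the smaller
    label (labels are scanned in ascending order and np.argmin keeps the
    first minimum).
    """
    labels = np.asarray(labels)
    within = np.asarray(within, dtype=bool)
    ids = np.unique(labels[labels > 0])
    out = np.asarray(labels, dtype=np.int64).copy()
    dist = np.full(labels.shape, np.inf)
    if ids.size == 0:
        return out, dist
    fill = within & (labels == 0)
    if ids.size <= 16:
        # exact smallest-label tie rule via per-label transforms
        dists = np.empty((ids.size,) + labels.shape)
        for k, lid in enumerate(ids):
            dists[k] = ndi.distance_transform_edt(labels != lid)
        best = np.argmin(dists, axis=0)
        out[fill] = ids[best[fill]]
        dist[fill] = np.take_along_axis(dists, best[None], axis=0)[0][fill]
    else:
        # one transform with feature indices; ties resolved by the
        # transform's scan order (deterministic, not smallest-label)
        d, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
        out[fill] = labels[ir[fill], ic[fill]]
        dist[fill] = d[fill]
    dist[labels > 0] = 0.0
    return out, dist


def nearest_seed_assignment(
    candidates: Iterable[tuple[int, int]],
    seeds: np.ndarray,
    mask: GeodesicMask | np.ndarray,
    metric: str = "geodesic",
    connectivity: int = 8,
) -> Mapping[tuple[int, int], int]:
    """Map each candidate pixel to the label of the nearest seed object.

    Distances are measured from the seed objects' current pixel sets
    (multi-source). Under the geodesic metric paths run through
    traversable pixels plus the candidate pixels themselves; candidates
    unreachable from every seed are left out of the mapping. Under the
    Euclidean metric obstacles are ignored and every candidate is
    assigned. Ties break toward the smaller label.
    """
    seeds = np.asarray(seeds)
    if not (seeds > 0).any():
        raise ValueError("no seeds")
    cand = list(candidates)
    cmask = np.zeros(seeds.shape, dtype=bool)
    for r, c in cand:
        if seeds[r, c] > 0:
            raise ValueError(f"candidate {(r, c)} is already a seed pixel")
        cmask[r, c] = True
    if metric == "geodesic":
        allowed = _as_traversable(mask) | cmask
        lab, dist = geodesic_label_spread(seeds, allowed, connectivity)
        return {
            (r, c): int(lab[r, c])
            for r, c in cand
            if np.isfinite(dist[r, c]) and lab[r, c] > 0
        }
    if metric == "euclidean":
        lab, _ = euclidean_label_spread(seeds, cmask)
        return {(r, c): int(lab[r, c]) for r, c in cand}
    raise ValueError(f"metric must be 'geodesic' or 'euclidean', got {metric!r}")
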