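"""Seeded region growing through percentile levels, mitotic detection,
and end-to-end segmentation assembly.

Growth starts from the seed objects and proceeds level by level over the
percentile bins of the ROI intensities: at every level the newly
unmasked bin of unassigned pixels is assigned simultaneously to the seed
object with the nearest current boundary (geodesic or Euclidean
distance), after which object boundaries are updated and the next bin is
taken, until all pixels are mapped. Non-traversable boundary pixels and
any walled-off enclaves are filled in a final pass so the output
partitions the whole ROI with no gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from fogbank.foreground import ForegroundParams, _structure, egt_foreground
from fogbank.geodesic import (
    GeodesicMask,
    build_geodesic_mask,
    euclidean_label_spread,
    geodesic_label_spread,
)
from fogbank.seeds import (
    HistogramSeedParams,
    NucleoliSeedParams,
    circularity,
    histogram_quantization_seeds,
    nucleoli_seeds,
    percentile_table,
)

__all__ = [
    "FogBankParams",
    "fogbank_grow",
    "detect_mitotic",
    "merge_mitotic",
    "fogbank_segment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FogBankParams:
    """Parameters of the full segmentation pipeline.

    ``quantize=False`` combined with ``grow_metric='euclidean'``
    reproduces the "wopg" ablation: growth over every distinct intensity
    with Euclidean assignment, i.e. without percentile quantization and
    without the geodesic mask.
    """

    boundary_percentile: float = 85.0
    boundary_polarity: str = "bright"
    seed_method: str = "histogram"
    histogram_params: HistogramSeedParams = field(default_factory=HistogramSeedParams)
    nucleoli_params: NucleoliSeedParams = field(default_factory=NucleoliSeedParams)
    grow_direction: str = "ascending"
    grow_metric: str = "geodesic"
    mitotic: bool = False
    mitotic_percentile: float = 97.0
    mitotic_circularity: float = 0.5
    mitotic_min_size: int = 30
    quantize: bool = True
    connectivity: int = 8
    foreground_params: ForegroundParams = field(default_factory=ForegroundParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.boundary_percentile <= 100.0:
            raise ValueError("boundary_percentile must be in [0, 100]")
        if not 50.0 < self.mitotic_percentile <= 100.0:
            raise ValueError("mitotic_percentile must be in (50, 100]")
        if not 0.0 <= self.mitotic_circularity <= 1.0:
            raise ValueError("mitotic_circularity must be in [0, 1]")
        if self.grow_direction not in ("ascending", "descending"):
            raise ValueError("grow_direction must be ascending|descending")
        if self.grow_metric not in ("geodesic", "euclidean"):
            raise ValueError("grow_metric must be geodesic|euclidean")
        if self.seed_method not in ("histogram", "nucleoli"):
            raise ValueError("seed_method must be histogram|nucleoli")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _grow_levels(img: np.ndarray, roi: np.ndarray, params: FogBankParams) -> np.ndarray:
    """Threshold sequence for level-by-level growth (ascending in the
    sweep order's own sense: each entry unmasks one more bin)."""
    if params.quantize:
        p = percentile_table(img, roi)
        levels = p[1:101]
    else:
        levels = np.unique(img[roi])
    if params.grow_direction == "descending":
        levels = levels[::-1]
    return levels


def _assign_batch(
    labels: np.ndarray,
    batch: np.ndarray,
    trav: np.ndarray,
    params: FogBankParams,
) -> np.ndarray:
    """Assign one bin of pixels to nearest objects, in place semantics."""
    if params.grow_metric == "geodesic":
        allowed = (trav & (labels > 0)) | batch
        lab, _ = geodesic_label_spread(labels, allowed, params.connectivity)
    else:
        lab, _ = euclidean_label_spread(labels, batch)
    return lab


def fogbank_grow(
    img: np.ndarray,
    seeds: np.ndarray,
    geo: GeodesicMask,
    params: FogBankParams | None = None,
) -> np.ndarray:
    """Grow seed objects into single-cell regions across intensity levels.

    Every traversable ROI pixel reachable from a seed ends up with that
    seed's label; growth sweeps the percentile bins in ``grow_direction``
    order, assigning each bin's pixels simultaneously to the object with
    the nearest boundary (ties to the smaller label). Afterwards the
    remaining ROI pixels — the non-traversable boundary walls and any
    enclaves sealed off from every seed — are attached to the nearest
    grown cell so the ROI is fully partitioned. The output label set
    equals the seed label set.
    """
    if params is None:
        params = FogBankParams()
    img = np.asarray(img, dtype=np.float64)
    seeds = np.asarray(seeds)
    if not (seeds > 0).any():
        raise ValueError("no seeds")
    roi = np.asarray(geo.roi, dtype=bool)
    trav = np.asarray(geo.traversable, dtype=bool)

    labels = seeds.astype(np.int64).copy()
    levels = _grow_levels(img, roi, params)
    ascending = params.grow_direction == "ascending"
    for thr in levels:
        if ascending:
            unmasked = img <= thr
        else:
            unmasked = img >= thr
        batch = unmasked & trav & (labels == 0)
        if not batch.any():
            continue
        labels = _assign_batch(labels, batch, trav, params)

    # mop up traversable pixels whose bin never unmasked them (strict
    # threshold corner cases) before the final wall pass
    left = trav & (labels == 0)
    if left.any():
        labels = _assign_batch(labels, left, trav, params)

    # final pass: walls and sealed enclaves join the nearest cell, with
    # the whole ROI traversable so every foreground pixel gets mapped
    rest = roi & (labels == 0)
    if rest.any():
        if params.grow_metric == "geodesic":
            lab, _ = geodesic_label_spread(labels, roi, params.connectivity)
        else:
            lab, _ = euclidean_label_spread(labels, rest)
        labels = lab
    return labels


def detect_mitotic(
    img: np.ndarray,
    roi: np.ndarray,
    params: FogBankParams | None = None,
) -> np.ndarray:
    """Detect bright round mitotic bodies.

    Components of pixels above the ``mitotic_percentile`` intensity of
    the ROI (97th by default) are kept when they are at least
    ``mitotic_min_size`` pixels and at least ``mitotic_circularity``
    round, and labeled 1..K.
    """
    if params is None:
        params = FogBankParams()
    img = np.asarray(img, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    out = np.zeros(img.shape, dtype=np.int64)
    if not roi.any():
        return out
    thr = np.percentile(img[roi], params.mitotic_percentile)
    bw = (img > thr) & roi
    comp, ncomp = ndi.label(bw, structure=_structure(params.connectivity))
    nxt = 1
    sizes = np.bincount(comp.ravel(), minlength=ncomp + 1)
    for cid in range(1, ncomp + 1):
        if sizes[cid] < params.mitotic_min_size:
            continue
        mask = comp == cid
        if circularity(mask) < params.mitotic_circularity:
            continue
        out[mask] = nxt
        nxt += 1
    return out


def merge_mitotic(cells: np.ndarray, mitotic: np.ndarray) -> np.ndarray:
    """Superimpose mitotic objects onto the cell mask.

    Each mitotic object takes a fresh label, overwriting the cell labels
    beneath it; all other pixels are unchanged. Output labels are
    renumbered 1..K contiguously (cells first, in ascending original
    label order, then mitotic objects).
    """
    cells = np.asarray(cells)
    mitotic = np.asarray(mitotic)
    if cells.shape != mitotic.shape:
        raise ValueError("shape mismatch between cell and mitotic masks")
    out = cells.astype(np.int64).copy()
    offset = int(cells.max())
    on = mitotic > 0
    out[on] = mitotic[on] + offset
    # renumber contiguously, preserving order
    ids = np.unique(out[out > 0])
    lut = np.zeros(int(out.max()) + 1, dtype=np.int64)
    lut[ids] = np.arange(1, ids.size + 1)
    return lut[out]


def fogbank_segment(
    img: np.ndarray,
    params: FogBankParams | None = None,
) -> np.ndarray:
    """Full pipeline: foreground -> geodesic mask -> seeds -> grow -> mitotic.

    Deterministic for fixed inputs and parameters. A blank image yields
    an all-zero label image; an image where seed detection finds nothing
    falls back to one label per foreground connected component.
    """
    if params is None:
        params = FogBankParams()
    img = np.asarray(img, dtype=np.float64)
    roi = egt_foreground(img, params.foreground_params)
    if not roi.any():
        return np.zeros(img.shape, dtype=np.int64)
    geo = build_geodesic_mask(
        img, roi, params.boundary_percentile, params.boundary_polarity
    )
    if params.seed_method == "histogram":
        seeds = histogram_quantization_seeds(
            img, roi, params.histogram_params, geo, params.connectivity
        )
    else:
        seeds = nucleoli_seeds(
            img, roi, params.nucleoli_params, geo, params.connectivity
        )
    n_seeds = int(len(np.unique(seeds[seeds > 0])))
    logger.info("detected %d seeds", n_seeds)
    if n_seeds == 0:
        comp, n = ndi.label(roi, structure=_structure(params.connectivity))
        logger.info("no seeds: falling back to %d foreground components", n)
        return comp.astype(np.int64)
    cells = fogbank_grow(img, seeds, geo, params)
    if params.mitotic:
        mit = detect_mitotic(img, roi, params)
        logger.info("detected %d mitotic objects", int(mit.max()))
        cells = merge_mitotic(cells, mit)
    else:
        cells = merge_mitotic(cells, np.zeros_like(cells))  # renumber 1..K
    return cells
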