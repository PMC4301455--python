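"""Confluent-sheet phantoms with exact ground truth.

Generates a blob-shaped colony tessellated into Voronoi cells around
minimum-spacing sampled centers, with bright thin membrane ridges along
every cell-cell interface and the colony rim, per-cell interior texture,
dark round nucleoli inside each cell, optional bright round mitotic
bodies, additive Gaussian noise, and a darker background. The returned
label image is the exact tessellation (ridge pixels keep the label of
the Voronoi cell they fall in), so metric tests are exact. All
randomness flows through one generator seeded by ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["SheetSpec", "make_confluent_sheet", "make_disk"]


@dataclass(frozen=True)
class SheetSpec:
    """Phantom description. Intensities follow bright-membrane phase
    contrast phenomenology: membrane > cell texture > nucleoli > background."""

    n_cells: int = 5
    shape: tuple[int, int] = (128, 128)
    membrane_intensity: float = 200.0
    membrane_width: int = 2
    cell_texture_mean: float = 100.0
    cell_texture_std: float = 4.0
    nucleoli_per_cell: int = 1
    nucleolus_radius: float = 3.0
    nucleolus_intensity: float = 40.0
    n_mitotic: int = 0
    mitotic_intensity: float = 240.0
    mitotic_radius: float = 5.0
    background_level: float = 20.0
    noise_std: float = 0.0
    integer_gray: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1")
        if self.nucleolus_radius <= 0 or self.mitotic_radius <= 0:
            raise ValueError("radii must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


def make_disk(
    radius: float,
    center: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean disk: pixels within ``radius`` of ``center`` (clipped to
    the image bounds)."""
    if radius < 0.5:
        raise ValueError("radius must be >= 0.5 (at least one pixel)")
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _colony_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Blob-shaped colony: a disk with a smooth low-order radial wobble."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    base = 0.38 * min(h, w)
    n_harm = 3
    amp = rng.uniform(0.02, 0.08, size=n_harm) * base
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    rr, cc = np.ogrid[:h, :w]
    theta = np.arctan2(rr - cy, cc - cx)
    radius = base + sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase))
    )
    return np.hypot(rr - cy, cc - cx) <= radius


def _sample_centers(
    colony: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing with minimum spacing; spacing relaxes on failure."""
    rs, cs = np.nonzero(colony)
    area = rs.size
    if n > area:
        raise ValueError(f"n_cells={n} exceeds colony area {area}")
    # keep centers off the rim so each cell has interior room
    interior = ndi.binary_erosion(colony, iterations=3)
    ri, ci = np.nonzero(interior)
    if ri.size < n:
        ri, ci = rs, cs
    spacing = 0.75 * np.sqrt(area / n)
    while True:
        order = rng.permutation(ri.size)
        chosen: list[tuple[int, int]] = []
        for k in order:
            p = (int(ri[k]), int(ci[k]))
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= spacing**2 for q in chosen):
                chosen.append(p)
                if len(chosen) == n:
                    return np.asarray(chosen)
        spacing *= 0.8
        if spacing < 1.0:
            raise ValueError(f"cannot place {n} centers in colony of area {area}")


def make_confluent_sheet(
    spec: SheetSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (image, truth labels, cell center coordinates).

    The truth label image is the Voronoi tessellation of the colony —
    every colony pixel, ridge pixels included, carries the label of its
    nearest center — and is unaffected by noise. Fully reproducible from
    ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    colony = _colony_mask(spec.shape, rng)
    centers = _sample_centers(colony, spec.n_cells, rng)

    rr, cc = np.nonzero(colony)
    d2 = (rr[:, None] - centers[None, :, 0]) ** 2 + (cc[:, None] - centers[None, :, 1]) ** 2
    nearest = np.argmin(d2, axis=1)
    truth = np.zeros((h, w), dtype=np.int64)
    truth[rr, cc] = nearest + 1

    # membranes: pixels within membrane_width of a label interface or rim
    grown = np.stack(
        [ndi.binary_dilation(truth == k, iterations=spec.membrane_width)
         for k in range(1, spec.n_cells + 1)]
    )
    interface = grown.sum(axis=0) >= 2
    rim = colony & ~ndi.binary_erosion(colony, iterations=spec.membrane_width)
    membrane = colony & (interface | rim)

    img = np.full((h, w), float(spec.background_level))
    # per-cell texture: cell mean plus a small per-cell offset
    offsets = rng.normal(0.0, spec.cell_texture_std, size=spec.n_cells)
    for k in range(spec.n_cells):
        img[truth == k + 1] = spec.cell_texture_mean + offsets[k]
    img[membrane] = spec.membrane_intensity

    # nucleoli: dark disks well inside each cell (away from membranes)
    nucleoli_centers = []
    for k in range(spec.n_cells):
        room = (truth == k + 1) & ~membrane
        room = ndi.binary_erosion(room, iterations=int(np.ceil(spec.nucleolus_radius)) + 1)
        ys, xs = np.nonzero(room)
        if ys.size == 0:
            ys, xs = np.nonzero((truth == k + 1) & ~membrane)
        if ys.size == 0:
            continue
        picks = rng.choice(ys.size, size=min(spec.nucleoli_per_cell, ys.size), replace=False)
        for pk in np.atleast_1d(picks):
            ctr = (int(ys[pk]), int(xs[pk]))
            nucleoli_centers.append(ctr)
            img[make_disk(spec.nucleolus_radius, ctr, spec.shape)] = spec.nucleolus_intensity

    # mitotic bodies: bright disks anywhere in the colony interior
    inter = ndi.binary_erosion(colony, iterations=int(np.ceil(spec.mitotic_radius)) + 2)
    ys, xs = np.nonzero(inter)
    for _ in range(spec.n_mitotic):
        if ys.size == 0:
            break
        pk = int(rng.integers(ys.size))
        ctr = (int(ys[pk]), int(xs[pk]))
        img[make_disk(spec.mitotic_radius, ctr, spec.shape)] = spec.mitotic_intensity

    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    if spec.integer_gray:  # cameras quantize; also bounds distinct levels
        img = np.round(img)

    return img, truth, centers
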