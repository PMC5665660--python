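"""Seeded cell segmentation via a region-based active contour.

The user marks each cell with one click. An octagonal stamp at each click
initializes a two-phase piecewise-constant active contour (morphological
Chan-Vese) on the preprocessed grayscale image; the converged foreground is
restricted to components containing at least one seed and split between
seeds by nearest-seed distance. Cells touching the image border are removed
(their droplet count would be incomplete), and the masks are dilated so
droplets hugging the membrane are still captured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from lipidquant.geometry import octagon_offsets
from lipidquant.image_io import SeedSet

#: a converged region smaller than this is a failed seed, not a cell
MIN_CELL_AREA_PX = 20

#: evolution stops when fewer than this fraction of region pixels change
CONVERGENCE_TOL = 1e-3

_CHECK_EVERY = 5  # iterations between convergence checks


@dataclass
class SegmentationParams:
    octagon_radius_px: int = 8
    max_iterations: int = 200
    smoothing: int = 1
    dilation_radius_px: int = 3

    def __post_init__(self) -> None:
        if self.octagon_radius_px <= 0:
            raise ValueError("octagon_radius_px must be > 0")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be > 0")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be >= 0")


@dataclass
class CellLabelMask:
    """Integer-labeled cell regions: 0 = background, labels 1..n_cells."""

    labels: np.ndarray
    seed_of: dict[int, tuple[int, int]]
    failed_seeds: list[tuple[int, int]] = field(default_factory=list)
    converged: bool = True

    @property
    def n_cells(self) -> int:
        return len(self.seed_of)

    def binary(self) -> np.ndarray:
        return self.labels > 0


def build_seed_mask(seeds: SeedSet, octagon_radius_px: int) -> np.ndarray:
    """Stamp a flat-top regular octagon at every seed; overlaps union."""
    if octagon_radius_px <= 0:
        raise ValueError("octagon_radius_px must be > 0")
    h, w = seeds.image_shape
    mask = np.zeros((h, w), dtype=bool)
    offsets = octagon_offsets(octagon_radius_px)
    for r, c in seeds.points:
        rr = offsets[:, 0] + r
        cc = offsets[:, 1] + c
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    return mask


# 3 x 3 line structuring elements of the morphological curvature operator
_LINES = [
    np.array(se, dtype=bool)
    for se in (
        [[0, 0, 0], [1, 1, 1], [0, 0, 0]],
        [[0, 1, 0], [0, 1, 0], [0, 1, 0]],
        [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
        [[0, 0, 1], [0, 1, 0], [1, 0, 0]],
    )
]


def _sup_inf(u: np.ndarray) -> np.ndarray:
    return np.max([ndi.minimum_filter(u, footprint=se) for se in _LINES], axis=0)


def _inf_sup(u: np.ndarray) -> np.ndarray:
    return np.min([ndi.maximum_filter(u, footprint=se) for se in _LINES], axis=0)


def _evolve_contour(
    img: np.ndarray, init: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, bool]:
    """Two-phase piecewise-constant (Chan-Vese) evolution, morphological
    implementation.

    Each iteration flips boundary pixels toward the phase whose mean
    intensity they are closer to, then applies the alternating
    sup-inf / inf-sup curvature smoothing. The parity of the smoothing
    alternation is derived from the iteration index, so the evolution is a
    pure function of (image, init, params). Stops early when the region
    changes by < CONVERGENCE_TOL of its pixels per iteration, averaged over
    a short block.
    """
    u = init.astype(np.uint8)
    img_f = img.astype(np.float64)
    parity = 0
    prev = u.copy()
    for it in range(1, params.max_iterations + 1):
        inside = u > 0
        n_in = int(inside.sum())
        n_out = u.size - n_in
        c1 = float(img_f[inside].mean()) if n_in else 0.0
        c0 = float(img_f[~inside].mean()) if n_out else 0.0
        # gradient magnitude of u marks the current boundary band
        gr, gc = np.gradient(u.astype(np.float64))
        band = (np.abs(gr) + np.abs(gc)) > 0
        force = (img_f - c1) ** 2 - (img_f - c0) ** 2
        u = np.where(band & (force < 0), 1, np.where(band & (force > 0), 0, u)).astype(np.uint8)
        for _ in range(params.smoothing):
            u = _sup_inf(_inf_sup(u)) if parity % 2 else _inf_sup(_sup_inf(u))
            parity += 1
        if it % _CHECK_EVERY == 0:
            changed = int(np.count_nonzero(u != prev))
            if changed < CONVERGENCE_TOL * max(int(u.sum()), 1) * _CHECK_EVERY:
                return u.astype(bool), True
            prev = u.copy()
    warnings.warn(
        f"active contour did not converge within {params.max_iterations} iterations"
    )
    return u.astype(bool), False


def segment_cells(
    img: np.ndarray, seeds: SeedSet, params: SegmentationParams | None = None
) -> CellLabelMask:
    """Segment one cell per seed from the preprocessed grayscale image.

    The converged foreground is hole-filled (droplets are brighter than
    cytoplasm and must not punch holes in the cell region), restricted to
    components containing a seed, and split between seeds sharing a
    component by nearest-seed distance (ties to the lower seed index).
    Seeds whose region ends up smaller than ``MIN_CELL_AREA_PX`` are
    recorded as failed rather than counted.
    """
    params = params or SegmentationParams()
    if len(seeds) == 0:
        raise ValueError("no seeds: seeded segmentation needs at least one click")
    seed_mask = build_seed_mask(seeds, params.octagon_radius_px)
    fg, converged = _evolve_contour(img, seed_mask, params)
    # a seed the contour abandoned entirely marks a failed cell; a seed on a
    # real cell stays inside the region, so only the single seed pixels are
    # restored (they join their region by 8-connectivity)
    for r, c in seeds.points:
        fg[r, c] = True
    fg = ndi.binary_fill_holes(fg)

    comp = cc_label(fg, connectivity=2)
    pts = np.asarray(seeds.points, dtype=np.intp)
    seed_comp = comp[pts[:, 0], pts[:, 1]]

    labels = np.zeros_like(comp, dtype=np.int32)
    areas: dict[int, int] = {}
    for comp_id in np.unique(seed_comp):
        if comp_id == 0:
            continue
        in_comp = comp == comp_id
        owners = np.flatnonzero(seed_comp == comp_id)
        if owners.size == 1:
            labels[in_comp] = owners[0] + 1
        else:
            rr, cc = np.nonzero(in_comp)
            # squared distance to each owning seed; argmin ties -> lower index
            d2 = (rr[:, None] - pts[owners, 0]) ** 2 + (cc[:, None] - pts[owners, 1]) ** 2
            labels[rr, cc] = owners[np.argmin(d2, axis=1)] + 1
    for i in range(len(seeds)):
        areas[i + 1] = int(np.count_nonzero(labels == i + 1))

    seed_of: dict[int, tuple[int, int]] = {}
    failed: list[tuple[int, int]] = []
    relabeled = np.zeros_like(labels)
    nxt = 0
    for i, pt in enumerate(seeds.points):
        old = i + 1
        if areas[old] < MIN_CELL_AREA_PX:
            failed.append(tuple(pt))
            continue
        nxt += 1
        relabeled[labels == old] = nxt
        seed_of[nxt] = tuple(pt)
    if failed:
        warnings.warn(f"{len(failed)} seed(s) produced no usable cell region")
    return CellLabelMask(labels=relabeled, seed_of=seed_of, failed_seeds=failed, converged=converged)


def remove_border_cells(mask: CellLabelMask) -> CellLabelMask:
    """Delete every label touching the image border; renumber consecutively."""
    lab = mask.labels
    border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    doomed = set(np.unique(border)) - {0}
    relabeled = np.zeros_like(lab)
    seed_of: dict[int, tuple[int, int]] = {}
    nxt = 0
    for old in sorted(mask.seed_of):
        if old in doomed:
            continue
        nxt += 1
        relabeled[lab == old] = nxt
        seed_of[nxt] = mask.seed_of[old]
    return CellLabelMask(
        labels=relabeled,
        seed_of=seed_of,
        failed_seeds=list(mask.failed_seeds),
        converged=mask.converged,
    )


def dilate_labels(mask: CellLabelMask, dilation_radius_px: int) -> CellLabelMask:
    """Dilate each label by a rasterized disk; contested pixels go to the
    nearest original label (Euclidean distance to the label's pre-dilation
    pixels, ties to the lower label id). Pre-dilation pixels never move."""
    if dilation_radius_px < 0:
        raise ValueError("dilation_radius_px must be >= 0")
    lab = mask.labels
    if dilation_radius_px == 0 or mask.n_cells == 0:
        return CellLabelMask(
            labels=lab.copy(),
            seed_of=dict(mask.seed_of),
            failed_seeds=list(mask.failed_seeds),
            converged=mask.converged,
        )
    labels_sorted = sorted(mask.seed_of)
    # distance from every pixel to each label's pixel set; argmin over the
    # label axis resolves ties toward the lower label id
    dists = np.stack(
        [ndi.distance_transform_edt(lab != lid) for lid in labels_sorted], axis=0
    )
    nearest = np.argmin(dists, axis=0)
    mind = np.min(dists, axis=0)
    out = np.zeros_like(lab)
    within = mind <= dilation_radius_px
    out[within] = np.asarray(labels_sorted, dtype=lab.dtype)[nearest[within]]
    return CellLabelMask(
        labels=out,
        seed_of=dict(mask.seed_of),
        failed_seeds=list(mask.failed_seeds),
        converged=mask.converged,
    )
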