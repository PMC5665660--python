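"""Synthetic two-channel confocal fields of view with known ground truth.

The generator emulates Nile-Red-stained monocytes as seen in a maximum
intensity projection: each cell is an ellipse with a bright phospholipid
membrane ring and a dim cytoplasm fill in the red channel; neutral-lipid
droplets are bright anti-aliased green disks strictly inside their cell;
some droplets are deliberately placed touching a neighbor to create
two- and three-droplet fused components; extracellular green artifact spots
and sensor noise (Poisson shot noise, then Gaussian read noise) complete
the image. Every rendered object is recorded in a ground-truth table so
pipeline output can be compared against exact expected counts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from lipidquant.geometry import rasterize_disk
from lipidquant.image_io import DEFAULT_CHANNEL_ROLES, FieldOfView, SeedSet

_SUPERSAMPLE = 4  # linear supersampling factor for anti-aliased edges


@dataclass
class SynthConfig:
    """Stated imaging world for the generator.

    Geometry defaults model monocytes at a 512^2 downscaled acquisition
    (~0.18 um/px): cell radii 35-55 px (monocyte radius 7-10 um), droplet
    radii 2-6 px (sub-cellular droplets), 6 cells per FOV (sparse seeding
    so cells do not cluster). Noise defaults are the stressed acquisition condition
    (read-noise SD 8 on 8-bit data, shot noise on, 5 extracellular artifact
    spots per FOV on average); clean renders must switch these off
    explicitly.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 6
    cell_radius_px_range: tuple[float, float] = (35.0, 55.0)
    droplet_rate: float = 8.0
    droplet_radius_px_range: tuple[float, float] = (2.0, 6.0)
    merge_fraction: float = 0.1
    artifact_rate: float = 5.0
    noise_sigma: float = 8.0
    poisson_noise: bool = True
    rng_seed: int = 0
    # rendering details
    edge_margin_px: float = 8.0  # min clearance of cell boundary from border; < 0 allows border cells
    membrane_intensity: int = 220
    cytoplasm_intensity: int = 90
    droplet_intensity: int = 210
    artifact_intensity: int = 230
    ring_width_px: float = 2.0
    axis_ratio_max: float = 1.5

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.droplet_rate < 0 or self.artifact_rate < 0:
            raise ValueError("rates must be >= 0")
        for lo, hi in (self.cell_radius_px_range, self.droplet_radius_px_range):
            if not 0 < lo <= hi:
                raise ValueError("radius ranges must satisfy 0 < min <= max")
        if not 0 <= self.merge_fraction <= 1:
            raise ValueError("merge_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class CellTruth:
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a >= b
    angle_rad: float
    droplet_count: int = 0

    @property
    def positive(self) -> bool:
        return self.droplet_count >= 1


@dataclass
class DropletTruth:
    center: tuple[float, float]
    radius: float
    cell_index: int
    cluster_index: int


@dataclass
class ClusterTruth:
    """One planned connected component: ``size`` is its expected multiplicity."""

    cell_index: int
    size: int
    droplet_indices: list[int]


@dataclass
class GroundTruth:
    cells: list[CellTruth] = field(default_factory=list)
    droplets: list[DropletTruth] = field(default_factory=list)
    clusters: list[ClusterTruth] = field(default_factory=list)
    artifacts: list[tuple[tuple[float, float], float]] = field(default_factory=list)

    @property
    def total_droplets(self) -> int:
        return len(self.droplets)

    @property
    def per_cell_counts(self) -> list[int]:
        return [c.droplet_count for c in self.cells]

    @property
    def n_positive(self) -> int:
        return sum(1 for c in self.cells if c.positive)

    @property
    def pct_positive(self) -> float:
        return 100.0 * self.n_positive / len(self.cells) if self.cells else 0.0


class _Ellipse:
    def __init__(self, center: tuple[float, float], a: float, b: float, angle: float):
        self.center = center
        self.a = a
        self.b = b
        self.cos = math.cos(angle)
        self.sin = math.sin(angle)

    def norm2(self, rr: np.ndarray, cc: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Squared normalized radius with semi-axes shrunk by ``shrink``."""
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        u = dc * self.cos + dr * self.sin
        v = -dc * self.sin + dr * self.cos
        a = max(self.a - shrink, 1e-9)
        b = max(self.b - shrink, 1e-9)
        return (u / a) ** 2 + (v / b) ** 2


def _subpixel_grid(lo: int, hi: int) -> np.ndarray:
    """Supersampled coordinates covering pixel centers lo..hi inclusive."""
    n = (hi - lo + 1) * _SUPERSAMPLE
    return lo - 0.5 + (np.arange(n) + 0.5) / _SUPERSAMPLE


def _paint_coverage(
    channel: np.ndarray, inside_fn, bbox: tuple[int, int, int, int], intensity: float
) -> None:
    """Max-combine ``intensity * coverage`` into ``channel`` over the bbox,
    with coverage from a supersampled membership test."""
    h, w = channel.shape
    rlo, rhi, clo, chi = bbox
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, h - 1), min(chi, w - 1)
    if rhi < rlo or chi < clo:
        return
    rs = _subpixel_grid(rlo, rhi)
    cs = _subpixel_grid(clo, chi)
    rr, cc = np.meshgrid(rs, cs, indexing="ij")
    sub = inside_fn(rr, cc).astype(np.float64)
    s = _SUPERSAMPLE
    cov = sub.reshape(rhi - rlo + 1, s, chi - clo + 1, s).mean(axis=(1, 3))
    patch = channel[rlo : rhi + 1, clo : chi + 1]
    np.maximum(patch, intensity * cov, out=patch)


def _place_cells(cfg: SynthConfig, rng: np.random.Generator) -> list[CellTruth]:
    h, w = cfg.image_size
    cells: list[CellTruth] = []
    tries = 0
    max_tries = 200 * max(cfg.n_cells, 1)
    while len(cells) < cfg.n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping cells in "
                f"{cfg.image_size}; reduce n_cells or enlarge the image"
            )
        tries += 1
        b = rng.uniform(*cfg.cell_radius_px_range)
        a = b * rng.uniform(1.0, cfg.axis_ratio_max)
        angle = rng.uniform(0, math.pi)
        margin = a + cfg.edge_margin_px
        lo_r, hi_r = margin, h - 1 - margin
        lo_c, hi_c = margin, w - 1 - margin
        if lo_r >= hi_r or lo_c >= hi_c:  # negative edge_margin_px path
            lo_r, hi_r, lo_c, hi_c = 0, h - 1, 0, w - 1
        r0 = rng.uniform(lo_r, hi_r)
        c0 = rng.uniform(lo_c, hi_c)
        ok = all(
            math.hypot(r0 - c.center[0], c0 - c.center[1]) >= a + c.semi_axes[0] + 4
            for c in cells
        )
        if ok:
            cells.append(CellTruth(center=(r0, c0), semi_axes=(a, b), angle_rad=angle))
    return cells


def _plan_clusters(n_droplets: int, merge_fraction: float, rng: np.random.Generator) -> list[int]:
    """Partition a cell's droplets into clusters of size 1, 2 or 3.

    ``merge_fraction`` is the fraction of *droplets* placed touching a
    neighbor: round(merge_fraction * n) droplets are grouped into pairs
    (occasionally triples), the rest stay single.
    """
    sizes: list[int] = []
    to_merge = int(round(merge_fraction * n_droplets))
    if to_merge == 1 and n_droplets >= 2:
        to_merge = 2
    while to_merge >= 2:
        size = 3 if (to_merge >= 3 and rng.random() < 1 / 3) else 2
        sizes.append(size)
        to_merge -= size
    sizes.extend([1] * (n_droplets - sum(sizes)))
    return sizes


def _place_droplets(
    cfg: SynthConfig, cells: list[CellTruth], rng: np.random.Generator
) -> tuple[list[DropletTruth], list[ClusterTruth]]:
    droplets: list[DropletTruth] = []
    clusters: list[ClusterTruth] = []
    dr_lo, dr_hi = cfg.droplet_radius_px_range
    for ci, cell in enumerate(cells):
        ell = _Ellipse(cell.center, cell.semi_axes[0], cell.semi_axes[1], cell.angle_rad)
        n_d = int(rng.poisson(cfg.droplet_rate))
        placed_in_cell: list[tuple[float, float, float]] = []  # (r, c, radius)

        def cluster_centers(size: int, radius: float) -> list[tuple[float, float]] | None:
            """Try to place one cluster; None if no room was found."""
            # touching with minimal overlap: deep enough that the rendered
            # disks stay 8-connected after thresholding, no deeper
            step = 2 * radius - 0.8
            # droplet disks keep >= 1 px clearance from the cell boundary so
            # no droplet pixel falls outside its owner in a clean render
            inner = radius + 1
            margin = inner + (size - 1) * step
            if min(cell.semi_axes) <= margin:
                return None
            for _ in range(300):
                theta = rng.uniform(0, 2 * math.pi)
                u = math.sqrt(rng.uniform(0, 1))
                du = u * (cell.semi_axes[0] - margin) * math.cos(theta)
                dv = u * (cell.semi_axes[1] - margin) * math.sin(theta)
                anchor = (
                    cell.center[0] + du * ell.sin + dv * ell.cos,
                    cell.center[1] + du * ell.cos - dv * ell.sin,
                )
                direction = rng.uniform(0, 2 * math.pi)
                pts = [
                    (
                        anchor[0] + i * step * math.sin(direction),
                        anchor[1] + i * step * math.cos(direction),
                    )
                    for i in range(size)
                ]
                in_cell = all(
                    float(
                        ell.norm2(np.array([p[0]]), np.array([p[1]]), shrink=inner)[0]
                    )
                    <= 1.0
                    for p in pts
                )
                if not in_cell:
                    continue
                # separate clusters: >= 3 px gap to every previously placed disk
                clear = all(
                    math.hypot(p[0] - q0, p[1] - q1) >= radius + qr + 3
                    for p in pts
                    for (q0, q1, qr) in placed_in_cell
                )
                if clear:
                    return pts
            return None

        for size in _plan_clusters(n_d, cfg.merge_fraction, rng):
            radius = rng.uniform(dr_lo, dr_hi)
            pts = cluster_centers(size, radius)
            if pts is None:
                continue  # crowded cell: drop the cluster, truth stays consistent
            idx0 = len(droplets)
            for p in pts:
                droplets.append(
                    DropletTruth(center=p, radius=radius, cell_index=ci, cluster_index=len(clusters))
                )
                placed_in_cell.append((p[0], p[1], radius))
            clusters.append(
                ClusterTruth(cell_index=ci, size=len(pts), droplet_indices=list(range(idx0, len(droplets))))
            )
            cell.droplet_count += len(pts)
    return droplets, clusters


def _place_artifacts(
    cfg: SynthConfig,
    cell_support: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[tuple[float, float], float]]:
    h, w = cfg.image_size
    out: list[tuple[tuple[float, float], float]] = []
    n = int(rng.poisson(cfg.artifact_rate))
    for _ in range(n):
        for _ in range(50):
            r0 = rng.uniform(0, h - 1)
            c0 = rng.uniform(0, w - 1)
            radius = rng.uniform(1.0, 3.0)
            # clearance > mask dilation radius so artifacts can never fall
            # inside even a dilated cell mask
            px = rasterize_disk((r0, c0), radius + 8, (h, w))
            if px.size and not cell_support[px[:, 0], px[:, 1]].any():
                out.append(((r0, c0), radius))
                break
    return out


def generate_fov(cfg: SynthConfig) -> tuple[FieldOfView, SeedSet, GroundTruth]:
    """Render one synthetic FOV; deterministic given ``cfg.rng_seed``.

    Returns the image (RGB uint8, phospholipid red / neutral lipid green),
    the seed set (true cell centroids, i.e. perfect clicks) and the ground
    truth.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    h, w = cfg.image_size
    red = np.zeros((h, w), dtype=np.float64)
    green = np.zeros((h, w), dtype=np.float64)

    cells = _place_cells(cfg, rng)
    droplets, clusters = _place_droplets(cfg, cells, rng)

    cell_support = np.zeros((h, w), dtype=bool)
    for cell in cells:
        ell = _Ellipse(cell.center, cell.semi_axes[0], cell.semi_axes[1], cell.angle_rad)
        a = cell.semi_axes[0]
        bbox = (
            int(math.floor(cell.center[0] - a - 2)),
            int(math.ceil(cell.center[0] + a + 2)),
            int(math.floor(cell.center[1] - a - 2)),
            int(math.ceil(cell.center[1] + a + 2)),
        )
        _paint_coverage(red, lambda rr, cc: ell.norm2(rr, cc) <= 1.0, bbox, cfg.cytoplasm_intensity)
        _paint_coverage(
            red,
            lambda rr, cc: (ell.norm2(rr, cc) <= 1.0)
            & (ell.norm2(rr, cc, shrink=cfg.ring_width_px) > 1.0),
            bbox,
            cfg.membrane_intensity,
        )
        rr, cc = np.mgrid[max(bbox[0], 0) : min(bbox[1], h - 1) + 1,
                          max(bbox[2], 0) : min(bbox[3], w - 1) + 1]
        cell_support[rr, cc] |= ell.norm2(rr, cc) <= 1.0

    for d in droplets:
        r0, c0 = d.center
        rad = d.radius
        bbox = (
            int(math.floor(r0 - rad - 2)),
            int(math.ceil(r0 + rad + 2)),
            int(math.floor(c0 - rad - 2)),
            int(math.ceil(c0 + rad + 2)),
        )
        _paint_coverage(
            green,
            lambda rr, cc: (rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad,
            bbox,
            cfg.droplet_intensity,
        )

    artifacts = _place_artifacts(cfg, cell_support, rng)
    for (r0, c0), rad in artifacts:
        bbox = (
            int(math.floor(r0 - rad - 2)),
            int(math.ceil(r0 + rad + 2)),
            int(math.floor(c0 - rad - 2)),
            int(math.ceil(c0 + rad + 2)),
        )
        _paint_coverage(
            green,
            lambda rr, cc: (rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad,
            bbox,
            cfg.artifact_intensity,
        )

    img = np.zeros((h, w, 3), dtype=np.float64)
    img[:, :, 0] = red
    img[:, :, 1] = green
    if cfg.poisson_noise:
        img = rng.poisson(img).astype(np.float64)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    fov = FieldOfView(
        pixels=pixels,
        channel_roles=dict(DEFAULT_CHANNEL_ROLES),
        source_path=f"synthetic(seed={cfg.rng_seed})",
    )
    seeds = SeedSet(
        points=[
            (int(round(c.center[0])), int(round(c.center[1]))) for c in cells
        ],
        image_shape=(h, w),
    )
    truth = GroundTruth(cells=cells, droplets=droplets, clusters=clusters, artifacts=artifacts)
    return fov, seeds, truth


def generate_dose_series(
    base: SynthConfig, rate_multipliers: list[float], fovs_per_arm: int = 1
) -> list[list[tuple[FieldOfView, SeedSet, GroundTruth]]]:
    """One batch of FOVs per droplet-rate multiplier (a dose arm).

    Seeds are derived deterministically from the base seed so arms differ
    and reruns reproduce.
    """
    if not rate_multipliers:
        raise ValueError("rate_multipliers must be non-empty")
    if any(m <= 0 for m in rate_multipliers):
        raise ValueError("rate_multipliers must be > 0")
    batches = []
    for ai, mult in enumerate(rate_multipliers):
        arm = []
        for fi in range(fovs_per_arm):
            cfg = dataclasses.replace(
                base,
                droplet_rate=base.droplet_rate * mult,
                rng_seed=(base.rng_seed + 100_003 * ai + 7919 * fi) % (2**31),
            )
            arm.append(generate_fov(cfg))
        batches.append(arm)
    return batches
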