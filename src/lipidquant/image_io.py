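"""Image, seed and result I/O plus maximum intensity projection.

Conventions
-----------
* Rasters are ``uint8`` arrays of shape (height, width, channels).
* Coordinates are 0-based ``(row, col)``, origin at the top-left.
* Channel semantics are carried explicitly in ``channel_roles``; by default
  the phospholipid (membrane) signal is the red channel (index 0) and the
  neutral-lipid (droplet) signal the green channel (index 1), matching the
  usual red/green display of Nile-Red two-channel acquisitions.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

DEFAULT_CHANNEL_ROLES = {"phospholipid": 0, "neutral_lipid": 1}

#: fixed column orders for the result tables
CELLS_COLUMNS = ["fov_id", "cell_label", "n_droplet_components", "ld_count", "is_positive", "flagged"]
FOV_COLUMNS = ["fov_id", "n_cells", "n_positive", "pct_positive", "total_lds", "lds_per_positive_cell"]


@dataclass
class FieldOfView:
    """One acquired image: (H, W, C) uint8 raster plus channel semantics."""

    pixels: np.ndarray
    channel_roles: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    pixel_size_um: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3:
            raise ValueError(f"pixels must be (H, W, C), got shape {px.shape}")
        h, w, c = px.shape
        if h < 1 or w < 1 or c < 1:
            raise ValueError(f"zero-sized image: shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        roles = self.channel_roles
        for role in ("neutral_lipid", "phospholipid"):
            if role not in roles:
                raise ValueError(f"channel_roles missing required role {role!r}")
            if not (0 <= roles[role] < c):
                raise ValueError(
                    f"channel_roles[{role!r}] = {roles[role]} outside {c}-channel image"
                )
        if roles["neutral_lipid"] == roles["phospholipid"]:
            raise ValueError("neutral_lipid and phospholipid must be distinct channels")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_roles[role]]

    def as_rgb(self) -> np.ndarray:
        """(H, W, 3) view with phospholipid in red, neutral lipid in green.

        Two-channel images are expanded with a zero blue channel.
        """
        h, w = self.shape
        rgb = np.zeros((h, w, 3), dtype=np.uint8)
        rgb[:, :, 0] = self.channel("phospholipid")
        rgb[:, :, 1] = self.channel("neutral_lipid")
        if self.pixels.shape[2] >= 3:
            used = {self.channel_roles["phospholipid"], self.channel_roles["neutral_lipid"]}
            spare = [i for i in range(self.pixels.shape[2]) if i not in used]
            if spare:
                rgb[:, :, 2] = self.pixels[:, :, spare[0]]
        return rgb


@dataclass
class ZStack:
    """Ordered z-slices with identical shape and channel roles."""

    slices: list[FieldOfView]
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a z-stack needs at least one slice")
        shape0 = self.slices[0].pixels.shape
        roles0 = self.slices[0].channel_roles
        for s in self.slices[1:]:
            if s.pixels.shape != shape0 or s.channel_roles != roles0:
                raise ValueError("all slices must share shape and channel roles")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")


@dataclass
class SeedSet:
    """User click coordinates marking cell centers (may be empty)."""

    points: list[tuple[int, int]]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.image_shape
        for i, (r, c) in enumerate(self.points):
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"seed {i} at ({r}, {c}) outside image of shape ({h}, {w})"
                )

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run of the deterministic pipeline."""

    inputs: list[str]
    config: dict
    software_version: str
    random_seed: int | None = None
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _to_uint8(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    warnings.warn(
        f"{path}: {arr.dtype if hasattr(arr, 'dtype') else 'non-8-bit'} input "
        f"rescaled to 8-bit by linear min-max mapping [{lo:g}, {hi:g}] -> [0, 255]"
    )
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) * 255.0 / (hi - lo)).astype(np.uint8)


def read_image(
    path: str | Path, channel_map: dict[str, int] | None = None
) -> FieldOfView:
    """Read a multi-channel TIFF (or PNG fixture) as a :class:`FieldOfView`.

    16-bit inputs are rescaled to 8-bit by a linear min-max map with a
    warning. Images with fewer channels than ``channel_map`` requires raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    roles = dict(channel_map) if channel_map is not None else dict(DEFAULT_CHANNEL_ROLES)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        raise ValueError(f"{path}: single-channel image, need >= 2 channels")
    if arr.ndim != 3:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    arr = _to_uint8(arr, str(path))
    return FieldOfView(pixels=arr, channel_roles=roles, source_path=str(path))


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    z_step_um: float | None = None,
) -> ZStack:
    """Read a multi-page TIFF as a :class:`ZStack` (pages = z-slices)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    roles = dict(channel_map) if channel_map is not None else dict(DEFAULT_CHANNEL_ROLES)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 3:  # single page (H, W, C)
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected (Z, H, W, C) stack, got shape {arr.shape}")
    arr = _to_uint8(arr, str(path))
    slices = [
        FieldOfView(pixels=arr[z], channel_roles=dict(roles), source_path=f"{path}[z={z}]")
        for z in range(arr.shape[0])
    ]
    return ZStack(slices=slices, z_step_um=z_step_um)


def max_intensity_projection(stack: ZStack) -> FieldOfView:
    """Per-pixel maximum over z — collapses a stack into one countable image."""
    data = np.stack([s.pixels for s in stack.slices], axis=0)
    first = stack.slices[0]
    return FieldOfView(
        pixels=data.max(axis=0),
        channel_roles=dict(first.channel_roles),
        pixel_size_um=first.pixel_size_um,
        source_path=first.source_path,
    )


def read_seeds(path: str | Path, image_shape: tuple[int, int]) -> SeedSet:
    """Read a ``row,col`` CSV of 0-based click coordinates.

    Duplicate points are dropped with a warning; out-of-bounds or malformed
    rows raise with the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    if not lines or [s.strip() for s in lines[0].split(",")][:2] != ["row", "col"]:
        raise ValueError(f"{path}: expected header 'row,col'")
    h, w = image_shape
    points: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            r, c = int(parts[0]), int(parts[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed seed at line {lineno}: {line!r}") from exc
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(
                f"{path}: seed ({r}, {c}) at line {lineno} outside image ({h}, {w})"
            )
        if (r, c) in seen:
            warnings.warn(f"{path}: duplicate seed ({r}, {c}) at line {lineno} dropped")
            continue
        seen.add((r, c))
        points.append((r, c))
    return SeedSet(points=points, image_shape=(h, w))


def write_results(
    summaries: Sequence, per_cell: Sequence[dict], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``fov_summary.csv`` and ``cells.csv`` with fixed column order.

    Floats are rendered with 6 significant digits. Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fov_rows = []
    for s in summaries:
        d = dataclasses.asdict(s) if dataclasses.is_dataclass(s) else dict(s)
        fov_rows.append({k: d.get(k) for k in FOV_COLUMNS})
    cell_rows = [{k: dict(rec).get(k) for k in CELLS_COLUMNS} for rec in per_cell]
    fov_df = pd.DataFrame(fov_rows, columns=FOV_COLUMNS)
    cell_df = pd.DataFrame(cell_rows, columns=CELLS_COLUMNS)
    fov_path = out_dir / "fov_summary.csv"
    cells_path = out_dir / "cells.csv"
    fov_df.to_csv(fov_path, index=False, float_format="%.6g")
    cell_df.to_csv(cells_path, index=False, float_format="%.6g")
    return fov_path, cells_path
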