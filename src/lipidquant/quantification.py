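"""Per-cell droplet attribution and FOV / sample summaries.

The three quantities the tool reports per field of view are the total cell
count, the number (and percentage) of lipid-positive cells, and the total
droplet count; "LDs per positive cell" averages over positive cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidquant.cell_segmentation import CellLabelMask
from lipidquant.droplet_segmentation import DropletComponent


@dataclass
class CellRecord:
    cell_label: int
    n_droplet_components: int = 0
    ld_count: int = 0
    is_positive: bool = False
    flagged: bool = False


@dataclass
class FOVSummary:
    fov_id: str
    n_cells: int
    n_positive: int
    pct_positive: float
    total_lds: int
    lds_per_positive_cell: float | None  # None when no cell is positive


@dataclass
class SampleSummary:
    """Unweighted aggregation of one sample's FOVs."""

    fovs: list[FOVSummary]
    mean_pct_positive: float = field(init=False)
    mean_lds_per_positive_cell: float | None = field(init=False)

    def __post_init__(self) -> None:
        if not self.fovs:
            raise ValueError("a sample needs at least one FOV")
        self.mean_pct_positive = float(np.mean([f.pct_positive for f in self.fovs]))
        defined = [
            f.lds_per_positive_cell
            for f in self.fovs
            if f.lds_per_positive_cell is not None
        ]
        self.mean_lds_per_positive_cell = float(np.mean(defined)) if defined else None

    def mean(self, field_name: str) -> float | None:
        vals = [
            getattr(f, field_name) for f in self.fovs if getattr(f, field_name) is not None
        ]
        return float(np.mean(vals)) if vals else None


def assign_droplets_to_cells(
    components: list[DropletComponent], mask: CellLabelMask
) -> list[DropletComponent]:
    """Attribute each component to the cell under its centroid.

    If the centroid falls on background (a concave cell outline), the cell
    with the largest pixel overlap wins; ties go to the lower label. A
    component with no overlap at all indicates background correction was
    skipped and is an internal error.
    """
    lab = mask.labels
    for comp in components:
        r = int(round(comp.centroid[0]))
        c = int(round(comp.centroid[1]))
        r = min(max(r, 0), lab.shape[0] - 1)
        c = min(max(c, 0), lab.shape[1] - 1)
        owner = int(lab[r, c])
        if owner == 0:
            overlap = lab[comp.pixels[:, 0], comp.pixels[:, 1]]
            ids, counts = np.unique(overlap[overlap > 0], return_counts=True)
            if ids.size == 0:
                raise RuntimeError(
                    "droplet component has zero overlap with any cell; "
                    "was background correction applied?"
                )
            owner = int(ids[np.argmax(counts)])  # np.unique sorts: ties -> lower label
        comp.cell_label = owner
    return components


def classify_positive_cells(
    mask: CellLabelMask, ld_mask: np.ndarray, components: list[DropletComponent] | None = None
) -> list[CellRecord]:
    """One record per cell; positive iff the cell mask overlaps >= 1 droplet
    pixel (the subtract-the-inverted-mask construction reduces to this).

    When ``components`` (already assigned to cells) are given, per-cell
    component and droplet counts are filled in.
    """
    if mask.labels.shape != ld_mask.shape:
        raise ValueError(
            f"shape mismatch: cells {mask.labels.shape} vs LD mask {ld_mask.shape}"
        )
    overlap_labels = np.unique(mask.labels[ld_mask.astype(bool)])
    positive = set(int(v) for v in overlap_labels if v > 0)
    records = {
        lid: CellRecord(cell_label=lid, is_positive=lid in positive)
        for lid in sorted(mask.seed_of)
    }
    if components is not None:
        for comp in components:
            rec = records.get(comp.cell_label)
            if rec is None:
                continue
            rec.n_droplet_components += 1
            rec.ld_count += comp.multiplicity
    return list(records.values())


def summarize_fov(records: list[CellRecord], fov_id: str = "") -> FOVSummary:
    """Aggregate one FOV's cell records; flagged cells leave all denominators."""
    usable = [r for r in records if not r.flagged]
    n_cells = len(usable)
    positives = [r for r in usable if r.is_positive]
    n_positive = len(positives)
    total_lds = sum(r.ld_count for r in usable)
    pct = 100.0 * n_positive / n_cells if n_cells else 0.0
    per_pos = (
        float(np.mean([r.ld_count for r in positives])) if n_positive else None
    )
    return FOVSummary(
        fov_id=fov_id,
        n_cells=n_cells,
        n_positive=n_positive,
        pct_positive=pct,
        total_lds=total_lds,
        lds_per_positive_cell=per_pos,
    )


def fold_change(sample: SampleSummary, baseline: SampleSummary, field_name: str) -> float:
    """Ratio of unweighted FOV means, sample over baseline."""
    num = sample.mean(field_name)
    den = baseline.mean(field_name)
    if den is None or den == 0:
        raise ValueError(f"baseline mean of {field_name!r} is zero or undefined")
    if num is None:
        raise ValueError(f"sample mean of {field_name!r} is undefined")
    return num / den
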