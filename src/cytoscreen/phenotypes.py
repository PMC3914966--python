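"""Rule-based phenotype classification and well-level aggregation.

A cell is *morphologically abnormal* when its cytoplasmic area exceeds
1350 µm², its nuclear area falls below 150 µm², or its mean nuclear
DNA-stain intensity exceeds 1500 units; it is *mitotic* when the maximum
nuclear phosphohistone-H3 intensity exceeds 1200 units. All four
comparisons are strict, and the two flags are independent — a cell may be
both abnormal and mitotic, since they derive from different channels.

Wells are summarised by three endpoints: cell number, % abnormal cells
and % mitotic cells (the mitotic index). Cells from all fields of a well
are pooled before summarisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .segmentation import CellFeatures

SUMMARY_COLUMNS = ["plate_id", "well_id", "n_cells", "pct_abnormal", "pct_mitotic"]

#: The three well-level endpoints.
ENDPOINTS = ("n_cells", "pct_abnormal", "pct_mitotic")


@dataclass
class ClassificationRules:
    """Thresholds of the abnormality and mitosis rules.

    ``cyto_area_mode`` selects what "cytoplasmic area" means: the full
    cell region (``"cell"``, default — the 1350 µm² default threshold is
    calibrated to this reading) or the cell-minus-nucleus ring
    (``"ring"``).
    """

    cyto_area_max_um2: float = 1350.0
    nuclear_area_min_um2: float = 150.0
    mean_dna_intensity_max: float = 1500.0
    mitotic_intensity_min: float = 1200.0
    cyto_area_mode: str = "cell"

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name == "cyto_area_mode":
                continue
            if not getattr(self, f.name) > 0:
                raise InputError(f"{f.name} must be positive")
        if self.cyto_area_mode not in ("cell", "ring"):
            raise InputError("cyto_area_mode must be 'cell' or 'ring'")


@dataclass
class PhenotypeFlags:
    abnormal: bool
    mitotic: bool


@dataclass
class WellSummary:
    """The three endpoints for one well; percentages are NaN when empty."""

    plate_id: str
    well_id: str
    n_cells: int
    pct_abnormal: float
    pct_mitotic: float


def _effective_cyto_area(f: CellFeatures, rules: ClassificationRules) -> float:
    if rules.cyto_area_mode == "ring":
        return f.cyto_area_um2 - f.nuclear_area_um2
    return f.cyto_area_um2


def classify_cell(f: CellFeatures, rules: ClassificationRules | None = None) -> PhenotypeFlags:
    """Apply the abnormality and mitosis rules to one cell.

    Raises :class:`InputError` on missing or non-finite features; boundary
    values (exactly at a threshold) are normal/non-mitotic.
    """
    rules = rules or ClassificationRules()
    vals = (
        f.cyto_area_um2,
        f.nuclear_area_um2,
        f.mean_dna_intensity,
        f.max_mitotic_intensity,
    )
    if any(v is None or not math.isfinite(v) for v in vals):
        raise InputError(f"cell {f.cell_id}: missing or non-finite feature values")
    abnormal = (
        _effective_cyto_area(f, rules) > rules.cyto_area_max_um2
        or f.nuclear_area_um2 < rules.nuclear_area_min_um2
        or f.mean_dna_intensity > rules.mean_dna_intensity_max
    )
    mitotic = f.max_mitotic_intensity > rules.mitotic_intensity_min
    return PhenotypeFlags(abnormal=abnormal, mitotic=mitotic)


def classify_frame(features: pd.DataFrame, rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Vectorised :func:`classify_cell` over a per-cell feature table.

    Returns a copy with boolean ``abnormal`` and ``mitotic`` columns.
    """
    rules = rules or ClassificationRules()
    required = [
        "cyto_area_um2",
        "nuclear_area_um2",
        "mean_dna_intensity",
        "max_mitotic_intensity",
    ]
    missing = [c for c in required if c not in features.columns]
    if missing:
        raise InputError(f"feature table is missing columns: {missing}")
    sub = features[required].to_numpy(dtype=float)
    if not np.all(np.isfinite(sub)):
        raise InputError("feature table contains missing or non-finite values")
    cyto = sub[:, 0] - (sub[:, 1] if rules.cyto_area_mode == "ring" else 0.0)
    out = features.copy()
    out["abnormal"] = (
        (cyto > rules.cyto_area_max_um2)
        | (sub[:, 1] < rules.nuclear_area_min_um2)
        | (sub[:, 2] > rules.mean_dna_intensity_max)
    )
    out["mitotic"] = sub[:, 3] > rules.mitotic_intensity_min
    return out


def summarize_well(
    cells: Sequence[CellFeatures], rules: ClassificationRules | None = None
) -> WellSummary:
    """Pool a well's cells into the three endpoints.

    All cells must share one (plate, well) identity. An empty input gives
    ``n_cells = 0`` with NaN percentages.
    """
    rules = rules or ClassificationRules()
    cells = list(cells)
    if not cells:
        return WellSummary("", "", 0, float("nan"), float("nan"))
    idents = {(c.plate_id, c.well_id) for c in cells}
    if len(idents) > 1:
        raise InputError(f"cells span multiple wells: {sorted(idents)}")
    plate_id, well_id = cells[0].plate_id, cells[0].well_id
    flags = [classify_cell(c, rules) for c in cells]
    n = len(cells)
    return WellSummary(
        plate_id=plate_id,
        well_id=well_id,
        n_cells=n,
        pct_abnormal=100.0 * sum(fl.abnormal for fl in flags) / n,
        pct_mitotic=100.0 * sum(fl.mitotic for fl in flags) / n,
    )


def summarize_wells(
    features: pd.DataFrame, rules: ClassificationRules | None = None
) -> pd.DataFrame:
    """Per-well endpoint table from a pooled per-cell feature table.

    Cells are grouped by (plate_id, well_id) across fields; the returned
    frame has columns ``plate_id, well_id, n_cells, pct_abnormal,
    pct_mitotic``, sorted by plate then well.
    """
    classified = classify_frame(features, rules)
    grouped = classified.groupby(["plate_id", "well_id"], sort=True)
    out = grouped.agg(
        n_cells=("cell_id", "size") if "cell_id" in classified.columns else ("abnormal", "size"),
        pct_abnormal=("abnormal", lambda s: 100.0 * s.mean()),
        pct_mitotic=("mitotic", lambda s: 100.0 * s.mean()),
    ).reset_index()
    return out[SUMMARY_COLUMNS]


def features_to_frame(cells: Iterable[CellFeatures]) -> pd.DataFrame:
    """Convert CellFeatures records to the canonical per-cell table."""
    from .segmentation import FEATURE_COLUMNS

    rows = [
        {
            "plate_id": c.plate_id,
            "well_id": c.well_id,
            "field_index": c.field_index,
            "cell_id": c.cell_id,
            "nuclear_area_um2": c.nuclear_area_um2,
            "cyto_area_um2": c.cyto_area_um2,
            "mean_dna_intensity": c.mean_dna_intensity,
            "max_mitotic_intensity": c.max_mitotic_intensity,
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
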