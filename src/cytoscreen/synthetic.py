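"""Ground-truthed synthetic data for the two pipeline entry points.

Two levels of realism are provided:

* **Rendered fields** — multi-channel rasters of well-separated elliptical
  cells (an osteosarcoma-monolayer-like regime) with known per-cell
  geometry and intensity, plus ground-truth label masks, for exercising
  the segmentation path end to end.
* **Sampled tables** — per-cell feature tables and well/plate endpoint
  tables drawn from documented distributions, for exercising the
  classification and screen-statistics paths at scale.

The default distributions are anchored to the assay this emulates:
negative-control nuclei have a lognormal area with median 270 µm² (inside
the typical 200–350 µm² band), mean DNA intensities far below the 1500-unit
abnormality cut, and maximum mitosis-marker intensities near 225 units;
abnormal sub-populations sit on the far side of each classification
threshold. Positive-control wells default to 54.6% of the negative-control
cell count with a 21% well-to-well CV. Everything is driven by a single
integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import InputError
from .phenotypes import SUMMARY_COLUMNS
from .segmentation import FEATURE_COLUMNS, FieldImage

PHENOTYPES = ("normal", "enlarged", "condensed", "dna_bright", "mitotic")

#: Default plate geometry: 96 wells, 12 fields/well, 4000 cells/well,
#: scaled down by `scale` (default 0.1) for fast simulation.
CELLS_PER_WELL = 4000
FIELDS_PER_WELL = 12
DEFAULT_SCALE = 0.1


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    center_px: tuple[float, float]
    nucleus_axes_px: tuple[float, float]
    cell_axes_px: tuple[float, float]
    orientation_rad: float
    dna_level: float
    mitotic_level: float
    phenotype_truth: str

    def __post_init__(self) -> None:
        if min(*self.nucleus_axes_px, *self.cell_axes_px) <= 0:
            raise InputError("ellipse axes must be positive")
        if (
            self.nucleus_axes_px[0] > self.cell_axes_px[0]
            or self.nucleus_axes_px[1] > self.cell_axes_px[1]
        ):
            raise InputError("cell ellipse must contain the nucleus ellipse")
        if self.phenotype_truth not in PHENOTYPES:
            raise InputError(f"unknown phenotype {self.phenotype_truth!r}")

    @property
    def nuclear_area_um2_at(self) -> float:  # pragma: no cover - helper
        raise AttributeError("use nuclear_area_um2(pixel_size_um)")

    def nuclear_area_um2(self, pixel_size_um: float) -> float:
        a, b = self.nucleus_axes_px
        return float(np.pi * a * b * pixel_size_um**2)

    def cell_area_um2(self, pixel_size_um: float) -> float:
        a, b = self.cell_axes_px
        return float(np.pi * a * b * pixel_size_um**2)


@dataclass
class NoiseModel:
    """Additive Gaussian read noise plus Poisson shot noise.

    Defaults keep the SNR high enough that segmentation performance
    reflects geometry rather than noise.
    """

    read_noise_sd: float = 3.0
    shot_noise: bool = True
    dna_background: float = 50.0
    cell_background: float = 30.0
    mitotic_background: float = 200.0


@dataclass
class EffectModel:
    """Well-level effect of a treatment (role or dose).

    ``cellcount_multiplier`` scales the expected cell count relative to the
    negative-control mean; ``abnormal_fraction``/``mitotic_fraction`` set
    the expected phenotype mix; ``well_cv_pct`` is the well-to-well CV of
    the realised count. ``ec50_uM``/``hill_coefficient`` scale the effect
    with dose via a Hill curve when doses are simulated.
    """

    cellcount_multiplier: float = 1.0
    abnormal_fraction: float = 0.03
    mitotic_fraction: float = 0.03
    well_cv_pct: float = 7.0
    ec50_uM: float | None = None
    hill_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.cellcount_multiplier <= 0:
            raise InputError("cellcount_multiplier must be > 0")
        for name in ("abnormal_fraction", "mitotic_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must be in [0, 1]")
        if self.abnormal_fraction + self.mitotic_fraction > 1:
            raise InputError("phenotype fractions must sum to <= 1")
        if self.well_cv_pct < 0:
            raise InputError("well_cv_pct must be >= 0")

    def at_dose(self, dose_uM: float, baseline: "EffectModel") -> "EffectModel":
        """Hill-interpolated effect between baseline (dose 0) and full effect."""
        if self.ec50_uM is None:
            return self
        h = self.hill_coefficient
        s = dose_uM**h / (dose_uM**h + self.ec50_uM**h)
        return replace(
            self,
            cellcount_multiplier=baseline.cellcount_multiplier
            + (self.cellcount_multiplier - baseline.cellcount_multiplier) * s,
            abnormal_fraction=baseline.abnormal_fraction
            + (self.abnormal_fraction - baseline.abnormal_fraction) * s,
            mitotic_fraction=baseline.mitotic_fraction
            + (self.mitotic_fraction - baseline.mitotic_fraction) * s,
        )


#: DMSO-like baseline: full cell count, ~3% abnormal, ~3% mitotic, 7% well CV.
NEGATIVE_CONTROL = EffectModel()

#: Taxol-like positive control: 54.6% of the DMSO cell count with a 21%
#: well CV, a large abnormal fraction and a raised mitotic index.
POSITIVE_CONTROL = EffectModel(
    cellcount_multiplier=0.546,
    abnormal_fraction=0.30,
    mitotic_fraction=0.08,
    well_cv_pct=21.0,
)


# ---------------------------------------------------------------------------
# per-cell feature distributions (units: µm² and raw intensity units)

_GEOMETRY = {
    # phenotype: (nuclear-area lognormal median, sigma), (cell-area median, sigma)
    "normal": ((270.0, 0.15), (820.0, 0.15)),
    "enlarged": ((330.0, 0.12), (2200.0, 0.15)),
    "condensed": ((100.0, 0.15), (500.0, 0.18)),
    "dna_bright": ((250.0, 0.15), (800.0, 0.15)),
    "mitotic": ((210.0, 0.15), (700.0, 0.15)),
}

_DNA_LEVEL = {  # mean DAPI intensity: (mean, sd)
    "normal": (600.0, 120.0),
    "enlarged": (520.0, 110.0),
    "condensed": (900.0, 140.0),
    "dna_bright": (2400.0, 300.0),
    "mitotic": (950.0, 140.0),
}

_MITOTIC_LEVEL = {  # max nuclear pHH3 intensity: (mean, sd)
    "normal": (225.0, 30.0),
    "enlarged": (225.0, 30.0),
    "condensed": (225.0, 30.0),
    "dna_bright": (225.0, 30.0),
    "mitotic": (1900.0, 220.0),
}


def _draw_lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def _phenotype_mix(effect: EffectModel) -> dict[str, float]:
    """Split the abnormal fraction equally over its three sub-phenotypes."""
    ab = effect.abnormal_fraction / 3.0
    mix = {
        "enlarged": ab,
        "condensed": ab,
        "dna_bright": ab,
        "mitotic": effect.mitotic_fraction,
    }
    mix["normal"] = 1.0 - sum(mix.values())
    return mix


def sample_phenotypes(n: int, effect: EffectModel, rng: np.random.Generator) -> np.ndarray:
    mix = _phenotype_mix(effect)
    return rng.choice(PHENOTYPES, size=n, p=[mix[p] for p in PHENOTYPES])


def simulate_well_features(
    n_cells_mean: float,
    effect: EffectModel = NEGATIVE_CONTROL,
    seed: int | np.random.Generator = 0,
    plate_id: str = "SIM",
    well_id: str = "A01",
    n_fields: int = FIELDS_PER_WELL,
) -> pd.DataFrame:
    """Sample one well's per-cell feature table with truth labels.

    The realised cell count is Poisson with mean ``n_cells_mean ×
    cellcount_multiplier × L`` where ``L`` is a lognormal well effect with
    CV ``well_cv_pct``. Returns the canonical feature columns plus a
    ``phenotype_truth`` column (drop it to obtain pipeline-format input).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cv = effect.well_cv_pct / 100.0
    sigma = np.sqrt(np.log1p(cv**2))
    well_factor = np.exp(rng.normal(-(sigma**2) / 2.0, sigma))  # mean-one lognormal
    n = int(rng.poisson(n_cells_mean * effect.cellcount_multiplier * well_factor))
    phen = sample_phenotypes(n, effect, rng)

    nuc = np.empty(n)
    cyto = np.empty(n)
    dna = np.empty(n)
    mit = np.empty(n)
    for p in PHENOTYPES:
        m = phen == p
        k = int(m.sum())
        if not k:
            continue
        (nm, ns), (cm, cs) = _GEOMETRY[p]
        nuc[m] = _draw_lognormal(rng, nm, ns, k)
        cyto[m] = np.maximum(_draw_lognormal(rng, cm, cs, k), nuc[m] * 1.2)
        dna[m] = np.maximum(rng.normal(*_DNA_LEVEL[p], size=k), 1.0)
        mit[m] = np.maximum(rng.normal(*_MITOTIC_LEVEL[p], size=k), 0.0)

    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "well_id": well_id,
            "field_index": rng.integers(1, n_fields + 1, size=n),
            "cell_id": np.arange(1, n + 1),
            "nuclear_area_um2": nuc,
            "cyto_area_um2": cyto,
            "mean_dna_intensity": dna,
            "max_mitotic_intensity": mit,
            "phenotype_truth": phen,
        },
        columns=FEATURE_COLUMNS + ["phenotype_truth"],
    )


# ---------------------------------------------------------------------------
# rendered fields


def sample_cell_truths(
    n_cells: int,
    shape_px: tuple[int, int],
    pixel_size_um: float,
    effect: EffectModel = NEGATIVE_CONTROL,
    min_spacing_px: float = 40.0,
    margin_px: int = 2,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> list[CellTruth]:
    """Place cells with a minimum centre-to-centre spacing (well-spaced regime).

    Raises :class:`InputError` when the requested density cannot be placed
    within ``max_tries`` dart throws per cell.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phen = sample_phenotypes(n_cells, effect, rng)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    truths: list[CellTruth] = []
    for p in phen:
        (nm, ns), (cm, cs) = _GEOMETRY[p]
        nuc_area_px = _draw_lognormal(rng, nm, ns, 1)[0] / pixel_size_um**2
        cell_area_px = max(
            _draw_lognormal(rng, cm, cs, 1)[0] / pixel_size_um**2, nuc_area_px * 1.4
        )
        ratio = rng.uniform(1.0, 1.3)
        nuc_b = np.sqrt(nuc_area_px / (np.pi * ratio))
        cell_b = np.sqrt(cell_area_px / (np.pi * ratio))
        a_cell = cell_b * ratio
        lo = margin_px + a_cell + 1
        for _ in range(max_tries):
            r = rng.uniform(lo, shape_px[0] - lo)
            c = rng.uniform(lo, shape_px[1] - lo)
            # cell ellipses must stay disjoint so ground truth matches the render
            if all(
                (r - r0) ** 2 + (c - c0) ** 2
                >= max(min_spacing_px, a_cell + rad0 + 2.0) ** 2
                for (r0, c0), rad0 in zip(centers, radii)
            ):
                break
        else:
            raise InputError(
                f"could not place {n_cells} cells with spacing {min_spacing_px}px "
                f"in a {shape_px} field"
            )
        centers.append((r, c))
        radii.append(a_cell)
        truths.append(
            CellTruth(
                center_px=(r, c),
                nucleus_axes_px=(nuc_b * ratio, nuc_b),
                cell_axes_px=(a_cell, cell_b),
                orientation_rad=rng.uniform(0, np.pi),
                dna_level=max(rng.normal(*_DNA_LEVEL[p]), 1.0),
                mitotic_level=max(rng.normal(*_MITOTIC_LEVEL[p]), 0.0),
                phenotype_truth=p,
            )
        )
    return truths


def _paint(mask: np.ndarray, truth: CellTruth, axes: tuple[float, float], label: int) -> None:
    rr, cc = draw_ellipse(
        truth.center_px[0],
        truth.center_px[1],
        axes[0],
        axes[1],
        shape=mask.shape,
        rotation=truth.orientation_rad,
    )
    mask[rr, cc] = label


def render_field(
    truths: Sequence[CellTruth],
    shape_px: tuple[int, int],
    pixel_size_um: float,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    plate_id: str = "SIM",
    well_id: str = "A01",
    field_index: int = 1,
    check_overlap: bool = True,
) -> tuple[FieldImage, np.ndarray, np.ndarray]:
    """Render one field and its ground-truth nucleus/cell label masks.

    The DNA channel carries the nucleus ellipses at each cell's DNA level;
    the whole-cell channel carries the cell ellipses at a moderate level
    with a brighter nuclear region; the mitosis channel carries the
    nucleus ellipses at the cell's mitosis-marker level over a background
    that sets the non-mitotic maximum near 225 units.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nuc_mask = np.zeros(shape_px, dtype=np.int32)
    cell_mask = np.zeros(shape_px, dtype=np.int32)
    for k, t in enumerate(truths, start=1):
        if check_overlap:
            before = int((nuc_mask > 0).sum())
            _paint(nuc_mask, t, t.nucleus_axes_px, k)
            rr, cc = np.nonzero(nuc_mask == k)
            if (nuc_mask > 0).sum() - before != len(rr):  # pragma: no cover - defensive
                raise InputError(f"nucleus {k} overlaps an earlier nucleus")
        else:
            _paint(nuc_mask, t, t.nucleus_axes_px, k)
        _paint(cell_mask, t, t.cell_axes_px, k)
    if check_overlap:
        counts = np.bincount(nuc_mask.ravel(), minlength=len(truths) + 1)
        if np.any(counts[1:] == 0):
            raise InputError("overlapping nuclei: a nucleus was fully painted over")
    # a nucleus always belongs to its own cell even under slight cell overlap
    cell_mask[nuc_mask > 0] = nuc_mask[nuc_mask > 0]

    dna = np.full(shape_px, noise.dna_background)
    cell = np.full(shape_px, noise.cell_background)
    mitotic = np.full(shape_px, noise.mitotic_background * 0.5)
    for k, t in enumerate(truths, start=1):
        nuc_px = nuc_mask == k
        cell_px = cell_mask == k
        dna[nuc_px] += t.dna_level
        cell[cell_px] += 300.0
        cell[nuc_px] += 150.0
        # below-threshold cells get a level completing to ~background max
        mitotic[nuc_px] += t.mitotic_level - noise.mitotic_background * 0.5

    channels = {}
    for name, img in (("dna", dna), ("cell", cell), ("mitotic", mitotic)):
        img = np.clip(img, 0, None)
        if noise.shot_noise:
            img = rng.poisson(img).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0, noise.read_noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0, None)

    fieldimg = FieldImage(
        plate_id=plate_id,
        well_id=well_id,
        field_index=field_index,
        channels=channels,
        pixel_size_um=pixel_size_um,
    )
    return fieldimg, nuc_mask, cell_mask


# ---------------------------------------------------------------------------
# simulated screens


def _well_ids() -> list[str]:
    return [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]


def _plate_layout_frame(
    plate_id: str, timepoint_h: int, compounds: Sequence[str | None]
) -> pd.DataFrame:
    """One 96-well plate: 8 negative + 8 positive controls in columns 1/12."""
    wells = _well_ids()
    controls = {f"{r}01": "negative_control" for r in "ABCD"}
    controls |= {f"{r}01": "positive_control" for r in "EFGH"}
    controls |= {f"{r}12": "negative_control" for r in "ABCD"}
    controls |= {f"{r}12": "positive_control" for r in "EFGH"}
    rows = []
    it = iter(compounds)
    for w in wells:
        if w in controls:
            rows.append((plate_id, w, controls[w], "", np.nan, timepoint_h, False))
        else:
            cid = next(it, None)
            if cid is None:
                rows.append((plate_id, w, "excluded", "", np.nan, timepoint_h, True))
            else:
                rows.append((plate_id, w, "compound", cid, 20.0, timepoint_h, False))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "well_id", "role", "compound_id", "dose_uM", "timepoint_h", "excluded"],
    )


#: Negative-control endpoint distributions (mean, sd) used for fast
#: well-level simulation; documented assumptions, not measured values.
NULL_ENDPOINTS = {
    "n_cells": (400.0, 28.0),  # 7% CV around 4000 cells/well at scale 0.1
    "pct_abnormal": (3.0, 0.8),
    "pct_mitotic": (3.0, 1.0),
}

POSITIVE_ENDPOINTS = {
    "n_cells": (400.0 * 0.546, 400.0 * 0.546 * 0.21),  # 54.6% of DMSO, 21% CV
    "pct_abnormal": (30.0, 3.0),
    "pct_mitotic": (8.0, 2.0),
}


def simulate_screen(
    n_compounds: int,
    hit_spec: Mapping[str, Mapping[str, float]] | None = None,
    n_replicates: int = 4,
    plates_per_batch: int = 9,
    timepoint_h: int = 24,
    seed: int | np.random.Generator = 0,
    null_endpoints: Mapping[str, tuple[float, float]] = NULL_ENDPOINTS,
    positive_endpoints: Mapping[str, tuple[float, float]] = POSITIVE_ENDPOINTS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a replicated screen at the well-summary level.

    ``hit_spec`` maps compound id → {endpoint: shift in negative-control
    SD units}; unlisted compounds are null (drawn from the
    negative-control distribution). Plates carry 8 negative and 8 positive
    controls each and are grouped into batches of ``plates_per_batch``
    (a 9-plate batch holds 72 negative controls). Returns
    ``(well_summaries, layout, truth)`` where truth lists every compound
    with its true per-endpoint shift and hit status.
    """
    if n_compounds < 1:
        raise InputError("n_compounds must be >= 1")
    if plates_per_batch < 1:
        raise InputError("plates_per_batch must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hit_spec = dict(hit_spec or {})
    compound_ids = [f"C{i:04d}" for i in range(1, n_compounds + 1)]
    unknown = set(hit_spec) - set(compound_ids)
    if unknown:
        raise InputError(f"hit_spec references unknown compounds: {sorted(unknown)}")

    # round-robin the replicate wells across plates
    slots = [cid for cid in compound_ids for _ in range(n_replicates)]
    per_plate = 96 - 16
    n_plates = int(np.ceil(len(slots) / per_plate))
    layouts = []
    for p in range(n_plates):
        batch = p // plates_per_batch + 1
        pid = f"B{batch:02d}P{p % plates_per_batch + 1:02d}"
        chunk = slots[p * per_plate : (p + 1) * per_plate]
        frame = _plate_layout_frame(pid, timepoint_h, chunk)
        frame["batch_id"] = f"B{batch:02d}"
        layouts.append(frame)
    layout = pd.concat(layouts, ignore_index=True)

    summaries = []
    for _, row in layout.iterrows():
        vals = {}
        for ep in ("n_cells", "pct_abnormal", "pct_mitotic"):
            mu, sd = null_endpoints[ep]
            if row["role"] == "positive_control":
                mu, sd = positive_endpoints[ep]
            elif row["role"] == "compound":
                shift = hit_spec.get(row["compound_id"], {}).get(ep, 0.0)
                mu = mu + shift * sd
            v = rng.normal(mu, sd)
            vals[ep] = max(v, 0.0) if ep != "n_cells" else max(int(round(v)), 0)
        summaries.append((row["plate_id"], row["well_id"], *vals.values()))
    well_summaries = pd.DataFrame(summaries, columns=SUMMARY_COLUMNS)

    truth_rows = []
    for cid in compound_ids:
        shifts = hit_spec.get(cid, {})
        for ep in ("n_cells", "pct_abnormal", "pct_mitotic"):
            truth_rows.append((cid, ep, shifts.get(ep, 0.0), abs(shifts.get(ep, 0.0)) > 0))
    truth = pd.DataFrame(truth_rows, columns=["compound_id", "endpoint", "shift_sd", "is_true_hit"])
    return well_summaries, layout, truth


def simulate_plate_summaries(
    n_neg: int,
    n_pos: int,
    seed: int | np.random.Generator = 0,
    endpoint_params: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Control-only test plates (for FP/FN and Z′ validation runs)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows, lay = [], []
    wells = _well_ids()
    if n_neg + n_pos > len(wells):
        raise InputError("control counts exceed one plate; split across plates")
    roles = ["negative_control"] * n_neg + ["positive_control"] * n_pos
    order = rng.permutation(len(roles))  # arbitrary (randomised) layout
    for i, j in enumerate(order):
        w = wells[i]
        role = roles[j]
        params = NULL_ENDPOINTS if role == "negative_control" else POSITIVE_ENDPOINTS
        if endpoint_params and role == "negative_control":
            params = endpoint_params
        vals = {ep: max(rng.normal(*params[ep]), 0.0) for ep in NULL_ENDPOINTS}
        rows.append(("TP01", w, *vals.values()))
        lay.append(("TP01", w, role, "", np.nan, 24, False))
    summaries = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    layout = pd.DataFrame(
        lay, columns=["plate_id", "well_id", "role", "compound_id", "dose_uM", "timepoint_h", "excluded"]
    )
    return summaries, layout
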