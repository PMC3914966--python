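"""Nucleus-seeded cell segmentation and per-cell feature extraction.

The segmentation strategy mirrors standard high-content practice: nuclei
are detected on the DNA-stain channel (Gaussian smoothing, global Otsu or
fixed threshold, hole filling, optional distance-transform watershed to
split touching nuclei), then one cell region is grown per nucleus on the
whole-cell-stain channel by an intensity-guided watershed seeded at the
nuclei and confined to the stain's foreground. Cells touching the image
border are excluded together with their nuclei, because their areas would
be censored. All areas are reported in µm² using the field's pixel size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .errors import ConsistencyError, InputError

log = logging.getLogger(__name__)

#: Channel keys every field must carry.
CHANNELS = ("dna", "cell", "mitotic")

#: Physical field of view (height, width) in µm at the nominal magnification.
FIELD_OF_VIEW_UM = (510.0, 675.0)

#: Column order of the per-cell feature table.
FEATURE_COLUMNS = [
    "plate_id",
    "well_id",
    "field_index",
    "cell_id",
    "nuclear_area_um2",
    "cyto_area_um2",
    "mean_dna_intensity",
    "max_mitotic_intensity",
]


@dataclass
class FieldImage:
    """One imaged field: three registered fluorescence channels.

    Parameters
    ----------
    plate_id, well_id, field_index
        Identity of the field within the screen (e.g. ``"P01"``, ``"B03"``, 1).
    channels
        Mapping with keys ``dna`` (nuclear stain), ``cell`` (whole-cell
        stain) and ``mitotic`` (mitosis marker), each a 2-D non-negative
        intensity raster of identical shape, raw detector units.
    pixel_size_um
        Physical edge length of one pixel in µm.
    """

    plate_id: str
    well_id: str
    field_index: int
    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise InputError(f"field is missing channels: {missing}")
        shapes = {c: np.asarray(self.channels[c]).shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise InputError(f"channel shapes differ: {shapes}")
        for name in CHANNELS:
            arr = np.asarray(self.channels[name], dtype=float)
            _validate_raster(arr, name)
            self.channels[name] = arr
        if not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be positive")
        if self.field_index < 1:
            raise InputError("field_index must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["dna"].shape


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation stage.

    Defaults are deliberately conservative: a 20 µm² debris filter (well
    below the 150 µm² nuclear-area classification boundary, so debris
    removal cannot absorb classification decisions), Otsu thresholds on
    both channels, and watershed splitting of touching nuclei enabled.
    """

    min_nucleus_area_um2: float = 20.0
    nucleus_threshold_method: str = "otsu"
    fixed_nucleus_threshold: float | None = None
    split_touching: bool = True
    split_min_distance_px: int = 8
    cell_threshold_method: str = "otsu"
    fixed_cell_threshold: float | None = None
    smoothing_sigma_px: float = 1.5
    halfmax_refine: bool = True

    def __post_init__(self) -> None:
        if self.min_nucleus_area_um2 < 0:
            raise InputError("min_nucleus_area_um2 must be >= 0")
        if self.smoothing_sigma_px < 0:
            raise InputError("smoothing_sigma_px must be >= 0")
        for attr in ("nucleus_threshold_method", "cell_threshold_method"):
            if getattr(self, attr) not in ("otsu", "fixed"):
                raise InputError(f"{attr} must be 'otsu' or 'fixed'")
        if self.nucleus_threshold_method == "fixed" and self.fixed_nucleus_threshold is None:
            raise InputError("fixed nucleus thresholding requires fixed_nucleus_threshold")
        if self.cell_threshold_method == "fixed" and self.fixed_cell_threshold is None:
            raise InputError("fixed cell thresholding requires fixed_cell_threshold")


@dataclass
class CellFeatures:
    """Measurements of one segmented cell, areas in µm², intensities raw.

    ``cyto_area_um2`` is the full cell region including the nucleus (see
    the classification rules for the alternative ring reading).
    """

    plate_id: str
    well_id: str
    field_index: int
    cell_id: int
    nuclear_area_um2: float
    cyto_area_um2: float
    mean_dna_intensity: float
    max_mitotic_intensity: float


def pixel_size_from_field_of_view(
    shape_px: tuple[int, int], field_um: tuple[float, float] = FIELD_OF_VIEW_UM
) -> float:
    """Derive µm/pixel from image dimensions and the physical field of view.

    Uses the mean of the row- and column-wise scales and warns if they
    disagree by more than 2% (anisotropic pixels are not supported).
    """
    sy = field_um[0] / shape_px[0]
    sx = field_um[1] / shape_px[1]
    if abs(sy - sx) > 0.02 * max(sy, sx):
        warnings.warn(
            f"anisotropic pixel scale ({sy:.4f} x {sx:.4f} um/px); using the mean",
            stacklevel=2,
        )
    return 0.5 * (sy + sx)


def _validate_raster(arr: np.ndarray, name: str = "raster") -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InputError(f"{name} must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    if arr.min() < 0:
        raise InputError(f"{name} contains negative intensities")
    return arr


def _smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return arr
    return gaussian(arr, sigma=sigma, preserve_range=True)


def _threshold(arr: np.ndarray, method: str, fixed: float | None) -> float | None:
    """Return the foreground threshold, or None when Otsu is degenerate."""
    if method == "fixed":
        return float(fixed)
    if arr.min() == arr.max():  # constant image: no signal, no objects
        return None
    return float(threshold_otsu(arr))


def segment_nuclei(
    dna: np.ndarray, pixel_size_um: float, params: SegmentationParams | None = None
) -> np.ndarray:
    """Detect nuclei on the DNA-stain channel.

    Returns an integer label mask (0 = background, 1..K = nuclei) with
    objects smaller than ``params.min_nucleus_area_um2`` removed. Objects
    touching the raster edge are retained here; border exclusion happens
    later, jointly with the grown cell regions.
    """
    params = params or SegmentationParams()
    dna = _validate_raster(dna, "dna channel")
    if not pixel_size_um > 0:
        raise InputError("pixel_size_um must be positive")

    smoothed = _smooth(dna, params.smoothing_sigma_px)
    thr = _threshold(smoothed, params.nucleus_threshold_method, params.fixed_nucleus_threshold)
    if thr is None:
        return np.zeros(dna.shape, dtype=np.int32)
    if params.nucleus_threshold_method == "otsu":
        # Otsu can sit above dim nuclei when brightness varies; a robust
        # background cut (median + 6 MAD) catches them, and the half-max
        # refinement restores per-object boundaries afterwards.
        med = float(np.median(smoothed))
        mad = float(np.median(np.abs(smoothed - med)))
        if mad > 0:
            thr = min(thr, med + 6.0 * 1.4826 * mad)
    binary = ndi.binary_fill_holes(smoothed > thr)

    min_px = int(np.ceil(params.min_nucleus_area_um2 / pixel_size_um**2))
    if params.split_touching:
        labels = _split_touching(binary, params.split_min_distance_px)
    else:
        labels, _ = ndi.label(binary)

    if params.halfmax_refine and labels.max() > 0:
        bg_level = float(np.median(smoothed[~binary])) if (~binary).any() else thr
        labels = _halfmax_refine(labels, smoothed, bg_level)

    labels = _remove_small(labels, min_px)
    return relabel_sequential(labels)


def _halfmax_refine(labels: np.ndarray, smoothed: np.ndarray, bg_level: float) -> np.ndarray:
    """Re-threshold each object at half its peak height above background.

    A global threshold biases object extent whenever objects differ in
    brightness (bright objects spill out under smoothing, dim ones
    shrink); for a Gaussian-blurred step edge the half-maximum contour
    sits at the true boundary, so a per-object half-peak threshold
    removes that bias. Only the largest connected piece of each object is
    kept.
    """
    out = np.zeros_like(labels, dtype=np.int32)
    grow = 6  # px a dim, under-thresholded object may expand beyond its seed
    objects = ndi.find_objects(labels)
    for sl, k in zip(objects, range(1, int(labels.max()) + 1)):
        if sl is None:
            continue
        pad = tuple(
            slice(max(s.start - grow, 0), min(s.stop + grow, dim))
            for s, dim in zip(sl, labels.shape)
        )
        m = labels[pad] == k
        peak = smoothed[pad][m].max()
        thr = bg_level + 0.5 * (peak - bg_level)
        # grow into unclaimed territory only, never into another object
        room = ndi.binary_dilation(m, iterations=grow) & (
            (labels[pad] == 0) | (labels[pad] == k)
        )
        keep = room & (smoothed[pad] > thr)
        pieces, n = ndi.label(keep)
        if n > 1:
            at_seed = np.unique(pieces[m & keep])
            at_seed = at_seed[at_seed > 0]
            if len(at_seed):
                keep = pieces == at_seed[0]
            else:
                sizes = np.bincount(pieces.ravel())
                keep = pieces == (np.argmax(sizes[1:]) + 1)
        out[pad][keep] = k
    return out


def _split_touching(binary: np.ndarray, min_dist: int) -> np.ndarray:
    """Watershed on the distance transform to separate touching nuclei."""
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    min_dist = max(3, int(min_dist))
    coords = peak_local_max(dist, min_distance=min_dist, labels=binary, exclude_border=False)
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    # merge duplicate peaks on plateaus of the same object
    markers, _ = ndi.label(ndi.binary_dilation(markers > 0, iterations=2) & binary)
    if markers.max() == 0:
        labels, _ = ndi.label(binary)
        return labels
    return watershed(-dist, markers=markers, mask=binary)


def _remove_small(labels: np.ndarray, min_px: int) -> np.ndarray:
    if labels.max() == 0 or min_px <= 1:
        return labels
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_px)
    out = labels.copy()
    out[np.isin(labels, small[small > 0])] = 0
    return out


def relabel_sequential(labels: np.ndarray, mapping: dict[int, int] | None = None) -> np.ndarray:
    """Relabel objects to a contiguous 1..K set (optionally with a given map)."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    if mapping is None:
        mapping = {old: new for new, old in enumerate(present, start=1)}
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return lut[labels]


def segment_cells(
    cell_channel: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Grow one cell region per nucleus on the whole-cell-stain channel.

    Cell regions share the label integer of their seed nucleus, are
    mutually disjoint, each contains its full nucleus, and are confined to
    the above-threshold foreground of the cell channel (union the nucleus
    pixels, so a nucleus is never orphaned by a dim cytoplasm). Boundaries
    between adjacent cells are placed by a watershed on the inverted
    smoothed intensity, i.e. along the dim valley between cells.
    """
    params = params or SegmentationParams()
    cell_channel = _validate_raster(cell_channel, "cell channel")
    nuclei = np.asarray(nuclei)
    if nuclei.shape != cell_channel.shape:
        raise InputError(
            f"nuclei mask shape {nuclei.shape} != cell channel shape {cell_channel.shape}"
        )
    if nuclei.max() == 0:
        return np.zeros(cell_channel.shape, dtype=np.int32)

    smoothed = _smooth(cell_channel, params.smoothing_sigma_px)
    thr = _threshold(smoothed, params.cell_threshold_method, params.fixed_cell_threshold)
    foreground = np.ones(cell_channel.shape, bool) if thr is None else smoothed > thr
    mask = foreground | (nuclei > 0)
    cells = watershed(-smoothed, markers=nuclei.astype(np.int32), mask=mask)

    # Watershed with markers cannot empty a seed region, but guard anyway.
    lost = set(np.unique(nuclei)) - set(np.unique(cells))
    lost.discard(0)
    if lost:  # pragma: no cover - defensive
        log.warning("dropped %d cells fully claimed by neighbours: %s", len(lost), sorted(lost))
    return cells.astype(np.int32)


def exclude_border_objects(
    nuclei: np.ndarray, cells: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove every cell whose region touches the raster edge, with its nucleus.

    Remaining objects are renumbered contiguously with pairing preserved.
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    _check_paired(nuclei, cells)
    border = np.unique(
        np.concatenate([cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]])
    )
    border = set(int(b) for b in border if b > 0)
    keep = [int(k) for k in np.unique(cells) if k > 0 and int(k) not in border]
    mapping = {old: new for new, old in enumerate(sorted(keep), start=1)}
    return relabel_sequential(nuclei, mapping), relabel_sequential(cells, mapping)


def _check_paired(nuclei: np.ndarray, cells: np.ndarray) -> None:
    nl = set(np.unique(nuclei)) - {0}
    cl = set(np.unique(cells)) - {0}
    if nl != cl:
        raise ConsistencyError(
            f"nucleus/cell label sets differ: only-nuclei={sorted(nl - cl)}, "
            f"only-cells={sorted(cl - nl)}"
        )


def extract_cell_features(
    fieldimg: FieldImage, nuclei: np.ndarray, cells: np.ndarray
) -> list[CellFeatures]:
    """Measure each retained cell.

    Nuclear and cell areas are pixel counts scaled by ``pixel_size_um²``;
    the DNA intensity is averaged and the mitosis-marker intensity maxed
    over the nucleus pixels, in raw detector units.
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    if nuclei.shape != fieldimg.shape or cells.shape != fieldimg.shape:
        raise InputError("mask shape does not match field shape")
    _check_paired(nuclei, cells)
    labels = [int(k) for k in np.unique(cells) if k > 0]
    if not labels:
        return []

    px_area = fieldimg.pixel_size_um**2
    dna = fieldimg.channels["dna"]
    mitotic = fieldimg.channels["mitotic"]
    idx = np.arange(1, max(labels) + 1)
    nuc_counts = np.bincount(nuclei.ravel(), minlength=idx.max() + 1)
    cell_counts = np.bincount(cells.ravel(), minlength=idx.max() + 1)
    mean_dna = ndi.mean(dna, labels=nuclei, index=idx)
    max_mit = ndi.maximum(mitotic, labels=nuclei, index=idx)

    out = []
    for k in labels:
        out.append(
            CellFeatures(
                plate_id=fieldimg.plate_id,
                well_id=fieldimg.well_id,
                field_index=fieldimg.field_index,
                cell_id=k,
                nuclear_area_um2=float(nuc_counts[k] * px_area),
                cyto_area_um2=float(cell_counts[k] * px_area),
                mean_dna_intensity=float(mean_dna[k - 1]),
                max_mitotic_intensity=float(max_mit[k - 1]),
            )
        )
    return out


def segment_field(
    fieldimg: FieldImage, params: SegmentationParams | None = None
) -> tuple[list[CellFeatures], np.ndarray, np.ndarray]:
    """Full per-field pipeline: nuclei -> cells -> border exclusion -> features."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(fieldimg.channels["dna"], fieldimg.pixel_size_um, params)
    cells = segment_cells(fieldimg.channels["cell"], nuclei, params)
    nuclei, cells = exclude_border_objects(nuclei, cells)
    return extract_cell_features(fieldimg, nuclei, cells), nuclei, cells
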