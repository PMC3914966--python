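import numpy as np
import pytest

from cytoscreen import segment_field
from cytoscreen.segmentation import CellFeatures
from cytoscreen import synthetic as syn

PIXEL_SIZE = 0.66
FIELD_SHAPE = (512, 512)


def make_cell(
    cyto=800.0,
    nuc=270.0,
    dna=600.0,
    phh3=200.0,
    plate="P1",
    well="A01",
    field=1,
    cell_id=1,
) -> CellFeatures:
    return CellFeatures(
        plate_id=plate,
        well_id=well,
        field_index=field,
        cell_id=cell_id,
        nuclear_area_um2=nuc,
        cyto_area_um2=cyto,
        mean_dna_intensity=dna,
        max_mitotic_intensity=phh3,
    )


@pytest.fixture(scope="session")
def rendered_field():
    """One rendered field with its ground truth, shared across tests."""
    truths = syn.sample_cell_truths(18, FIELD_SHAPE, PIXEL_SIZE, seed=7)
    fieldimg, nuc_truth, cell_truth = syn.render_field(
        truths, FIELD_SHAPE, PIXEL_SIZE, seed=77
    )
    return truths, fieldimg, nuc_truth, cell_truth


@pytest.fixture(scope="session")
def segmented_field(rendered_field):
    _, fieldimg, _, _ = rendered_field
    feats, nuclei, cells = segment_field(fieldimg)
    return fieldimg, feats, nuclei, cells


def draw_disk(shape, center, radius, value, background=10.0):
    img = np.full(shape, background)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return img
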