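import numpy as np
import pytest

from myospec.spectra import (
    MeasurementRecord,
    SpectralDataset,
    Spectrum,
    WavelengthGrid,
)


@pytest.fixture
def small_grid():
    """A 40-channel uniform grid, 400-790 nm (10 nm spacing)."""
    return WavelengthGrid(np.linspace(400.0, 790.0, 40))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(grid, matrix, groups, modality="AF", with_background=True, white=None):
    """Assemble a dataset from a matrix and per-row group labels."""
    references, reference_records = {}, {}
    bg_id = ""
    if with_background:
        bg_id = "BG1"
        references["BG1"] = Spectrum(grid, np.zeros(len(grid)), "raw")
        reference_records["BG1"] = MeasurementRecord("BG1", "BG")
    white_id = ""
    if white is not None:
        white_id = "WHITE1"
        references["WHITE1"] = Spectrum(grid, white, "raw")
        reference_records["WHITE1"] = MeasurementRecord("WHITE1", "WHITE", background_id=bg_id)
    labels = [
        MeasurementRecord(
            measurement_id=f"m{i}",
            modality=modality,
            group=g,
            muscle=g,
            animal_id=f"a{i}",
            replicate=1,
            background_id=bg_id,
            white_id=white_id,
        )
        for i, g in enumerate(groups)
    ]
    return SpectralDataset(
        grid=grid,
        matrix=np.asarray(matrix, dtype=float),
        labels=labels,
        class_field="group",
        references=references,
        reference_records=reference_records,
    )
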