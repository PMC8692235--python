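"""Core data containers for fiber-optic spectroscopy.

A spectrometer acquisition is a vector of detector counts on a fixed
wavelength grid.  All downstream analysis (calibration, smoothing, PCA,
classification) operates on these containers; measurements from one
instrument share a single :class:`WavelengthGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "STATES",
    "WavelengthGrid",
    "Spectrum",
    "MeasurementRecord",
    "SpectralDataset",
    "default_instrument_grid",
]

#: Processing states a spectrum moves through, in pipeline order.
STATES = ("raw", "calibrated", "smoothed", "windowed", "normalized")

#: Measurement modalities carried by dataset rows.
MODALITIES = ("AF", "DR")

#: Reserved modality values flagging reference columns (not dataset rows).
REFERENCE_MODALITIES = ("BG", "WHITE")

_SIDES = ("L", "R", "NA")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing detection wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self):  # frozen dataclass with array field: hash by identity
        return id(self)

    @property
    def median_spacing(self) -> float:
        """Median channel spacing in nm (grids are near-uniform in practice)."""
        if len(self) < 2:
            raise ValueError("spacing undefined for a single-channel grid")
        return float(np.median(np.diff(self.values)))

    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def default_instrument_grid(n_points: int = 3648, lo_nm: float = 345.0, hi_nm: float = 1041.0) -> WavelengthGrid:
    """The USB-spectrometer grid: 3648 uniformly spaced channels, 345-1041 nm."""
    return WavelengthGrid(np.linspace(lo_nm, hi_nm, n_points))


@dataclass
class Spectrum:
    """One acquisition: intensity per grid channel plus a processing state.

    Masked channels (e.g. where the white reference is too dim to divide by)
    are carried as NaN and excluded from smoothing averages and the
    normalization maximum.
    """

    grid: WavelengthGrid
    intensity: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("intensity must be a 1-D vector")
        if self.intensity.size != len(self.grid):
            raise ValueError(
                f"intensity length {self.intensity.size} does not match "
                f"grid length {len(self.grid)}"
            )
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    def with_intensity(self, intensity: np.ndarray, state: str) -> "Spectrum":
        return Spectrum(grid=self.grid, intensity=intensity, state=state)

    def with_grid(self, grid: WavelengthGrid, intensity: np.ndarray, state: str) -> "Spectrum":
        return Spectrum(grid=grid, intensity=intensity, state=state)


@dataclass
class MeasurementRecord:
    """Metadata for one acquisition column.

    ``modality`` is ``AF``/``DR`` for tissue measurements; the reserved
    values ``BG`` and ``WHITE`` flag background and white-reference columns,
    which are addressable references rather than dataset rows.
    """

    measurement_id: str
    modality: str
    group: str = "NA"
    muscle: str = "NA"
    animal_id: str = "NA"
    side: str = "NA"
    replicate: int = 1
    background_id: str = ""
    white_id: str = ""

    def validate(self) -> None:
        if self.modality not in MODALITIES + REFERENCE_MODALITIES:
            raise ValueError(
                f"{self.measurement_id}: modality {self.modality!r} not in "
                f"{MODALITIES + REFERENCE_MODALITIES}"
            )
        if self.side not in _SIDES:
            raise ValueError(f"{self.measurement_id}: side must be one of {_SIDES}")
        if int(self.replicate) < 1:
            raise ValueError(f"{self.measurement_id}: replicate must be >= 1")
        if self.modality == "DR" and not self.white_id:
            raise ValueError(
                f"{self.measurement_id}: DR measurements require a white_id"
            )

    def label(self, class_field: str) -> str:
        value = getattr(self, class_field)
        return str(value)


@dataclass
class SpectralDataset:
    """Labeled intensity matrix: one row per tissue measurement.

    Background and white-reference spectra live in ``references`` keyed by
    their measurement_id, so a record's ``background_id``/``white_id``
    resolve without being dataset rows.
    """

    grid: WavelengthGrid
    matrix: np.ndarray
    labels: list[MeasurementRecord]
    class_field: str | None = None
    references: dict[str, Spectrum] = field(default_factory=dict)
    reference_records: dict[str, MeasurementRecord] = field(default_factory=dict)
    state: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            self.matrix = self.matrix.reshape(len(self.labels), -1)
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but {len(self.labels)} labels"
            )
        if self.matrix.shape[1] != len(self.grid) and self.matrix.size > 0:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but grid has "
                f"{len(self.grid)} channels"
            )

    @property
    def n_measurements(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        for record in self.labels:
            record.validate()
            if record.background_id and record.background_id not in self.references:
                raise ValueError(
                    f"{record.measurement_id}: background_id "
                    f"{record.background_id!r} does not resolve to a reference"
                )
            if record.white_id and record.white_id not in self.references:
                raise ValueError(
                    f"{record.measurement_id}: white_id {record.white_id!r} "
                    "does not resolve to a reference"
                )

    def spectrum(self, index: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[index], state=self.state)

    def classes(self, class_field: str | None = None) -> np.ndarray:
        """Per-row class label under ``class_field`` (default: dataset's)."""
        field_name = class_field or self.class_field
        if field_name is None:
            raise ValueError("no class_field set on dataset and none given")
        return np.array([r.label(field_name) for r in self.labels])

    def subset(self, row_indices: Sequence[int], class_field: str | None = None) -> "SpectralDataset":
        idx = list(row_indices)
        return SpectralDataset(
            grid=self.grid,
            matrix=self.matrix[idx],
            labels=[replace(self.labels[i]) for i in idx],
            class_field=class_field or self.class_field,
            references=dict(self.references),
            reference_records=dict(self.reference_records),
            state=self.state,
        )
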