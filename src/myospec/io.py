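"""Reading and writing spectra and metadata tables.

Spectra are stored as a wide CSV: first column ``wavelength_nm``, one
further column per measurement (tissue, background, or white reference),
named by measurement_id.  Metadata is a second CSV with one row per
measurement_id.  One fixed dialect — UTF-8, comma delimiter, "." decimal
separator, 17-significant-digit floats — keeps round trips bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    MODALITIES,
    REFERENCE_MODALITIES,
    MeasurementRecord,
    SpectralDataset,
    Spectrum,
    WavelengthGrid,
)

__all__ = ["read_spectra", "write_spectra", "assemble_by_class", "METADATA_COLUMNS"]

METADATA_COLUMNS = [
    "measurement_id",
    "modality",
    "group",
    "muscle",
    "animal_id",
    "side",
    "replicate",
    "background_id",
    "white_id",
]

_FLOAT_FORMAT = "%.17g"  # enough digits for exact binary64 round-trip


def _record_from_row(row: pd.Series) -> MeasurementRecord:
    def s(key: str) -> str:
        value = row[key]
        return "" if pd.isna(value) else str(value)

    return MeasurementRecord(
        measurement_id=s("measurement_id"),
        modality=s("modality"),
        group=s("group") or "NA",
        muscle=s("muscle") or "NA",
        animal_id=s("animal_id") or "NA",
        side=s("side") or "NA",
        replicate=int(row["replicate"]) if not pd.isna(row["replicate"]) else 1,
        background_id=s("background_id"),
        white_id=s("white_id"),
    )


def read_spectra(spectra_path: str | Path, metadata_path: str | Path) -> SpectralDataset:
    """Load a wide spectra CSV plus its metadata table into a dataset.

    Columns whose metadata modality is ``BG`` or ``WHITE`` become
    addressable reference spectra; ``AF``/``DR`` columns become dataset
    rows.  Raises ``ValueError`` on unmatched measurement ids, a DR record
    without a white reference, or a non-increasing wavelength column.
    """
    spectra = pd.read_csv(spectra_path, encoding="utf-8", float_precision="round_trip")
    meta = pd.read_csv(metadata_path, encoding="utf-8", dtype={c: str for c in METADATA_COLUMNS if c != "replicate"})
    if spectra.columns[0] != "wavelength_nm":
        raise ValueError("first spectra column must be 'wavelength_nm'")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")

    grid = WavelengthGrid(spectra["wavelength_nm"].to_numpy(dtype=float))
    measurement_ids = list(spectra.columns[1:])
    meta_ids = list(meta["measurement_id"])
    unmatched = set(measurement_ids) ^ set(meta_ids)
    if unmatched:
        raise ValueError(f"measurement ids not shared by spectra and metadata: {sorted(unmatched)}")
    if len(set(meta_ids)) != len(meta_ids):
        raise ValueError("duplicate measurement_id in metadata")

    records = {row["measurement_id"]: _record_from_row(row) for _, row in meta.iterrows()}
    rows, labels = [], []
    references: dict[str, Spectrum] = {}
    reference_records: dict[str, MeasurementRecord] = {}
    for mid in measurement_ids:  # column order defines row order
        record = records[mid]
        column = spectra[mid].to_numpy(dtype=float)
        if record.modality in REFERENCE_MODALITIES:
            references[mid] = Spectrum(grid, column, state="raw")
            reference_records[mid] = record
        elif record.modality in MODALITIES:
            rows.append(column)
            labels.append(record)
        else:
            raise ValueError(f"{mid}: unknown modality {record.modality!r}")

    matrix = np.vstack(rows) if rows else np.empty((0, len(grid)))
    dataset = SpectralDataset(
        grid=grid,
        matrix=matrix,
        labels=labels,
        references=references,
        reference_records=reference_records,
    )
    dataset.validate()
    return dataset


def write_spectra(dataset: SpectralDataset, spectra_path: str | Path, metadata_path: str | Path) -> None:
    """Serialize a dataset to the wide-CSV pair read by :func:`read_spectra`."""
    columns: dict[str, np.ndarray] = {"wavelength_nm": dataset.grid.values}
    meta_rows: list[MeasurementRecord] = []
    for record, row in zip(dataset.labels, dataset.matrix):
        columns[record.measurement_id] = row
        meta_rows.append(record)
    for ref_id, spectrum in dataset.references.items():
        columns[ref_id] = spectrum.intensity
        meta_rows.append(
            dataset.reference_records.get(
                ref_id, MeasurementRecord(measurement_id=ref_id, modality="BG")
            )
        )

    pd.DataFrame(columns).to_csv(spectra_path, index=False, float_format=_FLOAT_FORMAT, encoding="utf-8")
    meta = pd.DataFrame(
        [
            {
                "measurement_id": r.measurement_id,
                "modality": r.modality,
                "group": r.group,
                "muscle": r.muscle,
                "animal_id": r.animal_id,
                "side": r.side,
                "replicate": r.replicate,
                "background_id": r.background_id,
                "white_id": r.white_id,
            }
            for r in meta_rows
        ],
        columns=METADATA_COLUMNS,
    )
    meta.to_csv(metadata_path, index=False, encoding="utf-8")


def assemble_by_class(
    dataset: SpectralDataset, class_field: str, levels: list[str]
) -> SpectralDataset:
    """Restrict a dataset to the named class levels, preserving row order.

    Duplicate levels are collapsed (set semantics, first occurrence wins).
    Raises on a level with no rows, since a named but empty class would
    silently vanish from every downstream comparison.
    """
    seen: list[str] = []
    for level in levels:
        if level not in seen:
            seen.append(level)
    classes = dataset.classes(class_field)
    for level in seen:
        if not np.any(classes == level):
            raise ValueError(f"class level {level!r} has no rows under field {class_field!r}")
    keep = [i for i, c in enumerate(classes) if c in seen]
    return dataset.subset(keep, class_field=class_field)
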