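"""Spectral calibration and conditioning.

The chain, applied in this fixed order, is:

1. background subtraction, ``X = XR - B`` (both modalities), removing
   ambient room light;
2. for diffuse reflectance only, division by the background-corrected PTFE
   white reference, ``X = (XR - B) / W``, removing the lamp spectrum;
3. a 10-nm centered moving average;
4. windowing to 435-900 nm (AF) or 450-900 nm (DR) to drop the noisy
   spectral extremes;
5. peak normalization ``XN = X / max(X)``, so analysis sees spectral shape
   rather than absolute intensity (robust to probe contact and source
   power drift).

Negative calibrated values are kept, not clipped: clipping would bias the
moving-average mean.  Channels where the white reference is too dim to
divide by are masked as NaN and excluded from averages and the maximum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .spectra import MeasurementRecord, SpectralDataset, Spectrum, WavelengthGrid

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "calibrate_dr",
    "smooth",
    "window",
    "normalize_max",
    "preprocess_measurement",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    ``white_floor`` is expressed as a fraction of the white reference's
    maximum; channels dimmer than that are masked rather than divided by.
    ``white_background_corrected`` records whether the PTFE spectrum has
    its own background subtracted before division (default yes — ambient
    light contaminates the reference just as it does the tissue signal).
    """

    smooth_window_nm: float = 10.0
    af_window_nm: tuple[float, float] = (435.0, 900.0)
    dr_window_nm: tuple[float, float] = (450.0, 900.0)
    white_floor: float = 1e-6
    white_background_corrected: bool = True
    max_masked_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.smooth_window_nm <= 0:
            raise ValueError("smooth_window_nm must be positive")
        for lo, hi in (self.af_window_nm, self.dr_window_nm):
            if not lo < hi:
                raise ValueError("window bounds must satisfy lo < hi")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["af_window_nm"] = list(self.af_window_nm)
        d["dr_window_nm"] = list(self.dr_window_nm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        for key in ("af_window_nm", "dr_window_nm"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


def _require_same_grid(*spectra: Spectrum) -> None:
    first = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != first:
            raise ValueError("spectra are not on the same wavelength grid")


def subtract_background(tissue: Spectrum, background: Spectrum) -> Spectrum:
    """``X = XR - B``; negative values are noise and are kept."""
    _require_same_grid(tissue, background)
    return tissue.with_intensity(tissue.intensity - background.intensity, "calibrated")


def calibrate_dr(
    tissue: Spectrum,
    background: Spectrum,
    white: Spectrum,
    *,
    white_floor: float = 1e-6,
    check_window_nm: tuple[float, float] = (450.0, 900.0),
    max_masked_fraction: float = 0.2,
) -> Spectrum:
    """``X = (XR - B) / W`` with a division guard on dim white channels.

    ``white`` is the background-corrected PTFE reference.  Channels where
    ``W`` falls below ``white_floor * max(W)`` are masked (NaN).  If more
    than ``max_masked_fraction`` of the channels inside the analysis window
    are masked the calibration is considered unusable and a ``ValueError``
    is raised.
    """
    _require_same_grid(tissue, background, white)
    w = white.intensity
    floor = white_floor * float(np.nanmax(w))
    masked = ~(w >= floor)  # also masks NaN in the white itself
    numerator = tissue.intensity - background.intensity
    out = np.where(masked, np.nan, numerator / np.where(masked, 1.0, w))

    lam = tissue.grid.values
    in_window = (lam >= check_window_nm[0]) & (lam <= check_window_nm[1])
    if in_window.any():
        frac = float(masked[in_window].mean())
        if frac > max_masked_fraction:
            raise ValueError(
                f"{frac:.1%} of channels in {check_window_nm} nm are below the "
                "white-reference floor; calibration rejected"
            )
    return tissue.with_intensity(out, "calibrated")


def _half_width_samples(grid: WavelengthGrid, window_nm: float) -> int:
    spacing = grid.median_spacing
    if window_nm < spacing:
        raise ValueError(
            f"smoothing window {window_nm} nm is smaller than the grid "
            f"spacing {spacing:.4g} nm"
        )
    return int(round(window_nm / (2.0 * spacing)))


def moving_average_matrix(matrix: np.ndarray, half_width: int) -> np.ndarray:
    """Centered moving average along rows with a symmetrically shrinking
    window at the edges; NaN channels are excluded from neighbours' averages
    and stay NaN themselves."""
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = x.shape[1]
    valid = np.isfinite(x)
    filled = np.where(valid, x, 0.0)

    csum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(filled, axis=1)], axis=1)
    ccount = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(valid, axis=1)], axis=1)

    idx = np.arange(n)
    h = np.minimum(half_width, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    sums = csum[:, hi] - csum[:, lo]
    counts = ccount[:, hi] - ccount[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    out[~valid] = np.nan  # preserve the mask
    return out if np.asarray(matrix).ndim == 2 else out[0]


def smooth(spectrum: Spectrum, window_nm: float = 10.0) -> Spectrum:
    """Moving average over a window of ``window_nm`` nanometres.

    The window is an odd number of samples (centre plus equal half-widths
    of ``round(window_nm / (2 * median spacing))`` samples) and shrinks
    symmetrically at the spectrum edges, so the filter stays phase-free
    and never fabricates data beyond the grid.
    """
    h = _half_width_samples(spectrum.grid, window_nm)
    return spectrum.with_intensity(moving_average_matrix(spectrum.intensity, h), "smoothed")


def window(spectrum: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Retain channels with ``lo_nm <= lambda <= hi_nm`` (closed interval)."""
    if not lo_nm < hi_nm:
        raise ValueError("window bounds must satisfy lo < hi")
    lam = spectrum.grid.values
    keep = (lam >= lo_nm) & (lam <= hi_nm)
    if not keep.any():
        raise ValueError(f"window [{lo_nm}, {hi_nm}] nm retains no channels")
    return Spectrum(WavelengthGrid(lam[keep]), spectrum.intensity[keep], state="windowed")


def normalize_max(spectrum: Spectrum) -> Spectrum:
    """``XN = X / max(X)``; the maximum becomes exactly 1.

    Negative channels are scaled, not clipped.  Fails when the maximum is
    not positive (an all-noise or fully masked spectrum has no meaningful
    shape to normalize).
    """
    peak = float(np.nanmax(spectrum.intensity)) if np.isfinite(spectrum.intensity).any() else np.nan
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("cannot normalize: spectrum maximum is not positive")
    return spectrum.with_intensity(spectrum.intensity / peak, "normalized")


def _resolve_reference(dataset: SpectralDataset, ref_id: str, what: str) -> Spectrum:
    try:
        return dataset.references[ref_id]
    except KeyError:
        raise ValueError(f"{what} {ref_id!r} not found among dataset references") from None


def corrected_white(
    record: MeasurementRecord, dataset: SpectralDataset, config: PreprocessConfig
) -> Spectrum:
    """The white reference ready for division, background-corrected if the
    config says so (using the white's own background when it has one, else
    the measurement's)."""
    white = _resolve_reference(dataset, record.white_id, "white_id")
    if not config.white_background_corrected:
        return white
    white_record = dataset.reference_records.get(record.white_id)
    bg_id = (white_record.background_id if white_record and white_record.background_id else record.background_id)
    background = _resolve_reference(dataset, bg_id, "background_id")
    return subtract_background(white, background)


def preprocess_measurement(
    record: MeasurementRecord,
    dataset: SpectralDataset,
    config: PreprocessConfig = PreprocessConfig(),
    *,
    row: np.ndarray | None = None,
) -> Spectrum:
    """Run the full chain for one measurement.

    AF: subtract -> smooth -> window 435-900 -> normalize.
    DR: subtract & divide white -> smooth -> window 450-900 -> normalize.
    """
    if row is None:
        index = next(
            i for i, r in enumerate(dataset.labels) if r.measurement_id == record.measurement_id
        )
        row = dataset.matrix[index]
    tissue = Spectrum(dataset.grid, row, state="raw")
    background = _resolve_reference(dataset, record.background_id, "background_id")

    if record.modality == "AF":
        calibrated = subtract_background(tissue, background)
        lo, hi = config.af_window_nm
    elif record.modality == "DR":
        white = corrected_white(record, dataset, config)
        calibrated = calibrate_dr(
            tissue,
            background,
            white,
            white_floor=config.white_floor,
            check_window_nm=config.dr_window_nm,
            max_masked_fraction=config.max_masked_fraction,
        )
        lo, hi = config.dr_window_nm
    else:
        raise ValueError(f"cannot preprocess modality {record.modality!r}")

    smoothed = smooth(calibrated, config.smooth_window_nm)
    return normalize_max(window(smoothed, lo, hi))


def preprocess_dataset(
    dataset: SpectralDataset, config: PreprocessConfig = PreprocessConfig()
) -> SpectralDataset:
    """Preprocess every row of a single-modality dataset.

    Returns a new dataset on the windowed grid whose rows are normalized
    spectra, ready for PCA and statistics.
    """
    modalities = {r.modality for r in dataset.labels}
    if len(modalities) != 1:
        raise ValueError(f"dataset mixes modalities {sorted(modalities)}; preprocess one at a time")

    processed = [
        preprocess_measurement(record, dataset, config, row=row)
        for record, row in zip(dataset.labels, dataset.matrix)
    ]
    grid = processed[0].grid
    return SpectralDataset(
        grid=grid,
        matrix=np.vstack([s.intensity for s in processed]),
        labels=dataset.labels,
        class_field=dataset.class_field,
        state="normalized",
    )
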