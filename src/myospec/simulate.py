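"""Physics-based forward simulation of fiber-optic tissue spectra.

The generator emulates what the spectrometer records from a probe in
contact with muscle:

* **Autofluorescence (AF).**  Endogenous fluorophores (collagen, flavins
  such as FAD, porphyrins, lipofuscin) emit Gaussian bands; the summed
  emission is attenuated on its way back to the fiber by tissue
  chromophores (oxy/deoxy heme proteins) via a Beer-Lambert factor,
  because a fiber-optic AF signal is a hybrid of fluorescence and the
  same scattering/absorption processes that shape diffuse reflectance.

* **Diffuse reflectance (DR).**  The lamp spectrum ``W(lambda)`` is
  returned scaled by a power-law scattering term
  ``S(lambda) = a (lambda/500 nm)^-b`` and the chromophore Beer-Lambert
  attenuation; heme absorption carves the 500-600 nm bands and a weaker
  ~760 nm deoxy feature.

* **Instrument.**  Per-acquisition multiplicative gain jitter (lognormal;
  models probe-contact and source-power variability), a flat ambient
  background, and additive Gaussian read noise.  Concentrations vary
  between samples lognormally (mean + CV), so they stay positive.

All magnitudes are synthetic modeling choices — no quantitative optical
coefficients for these tissue classes are available — anchored only to
qualitative band positions (fluorophore variance loci at 475/550/650 nm,
heme bands at 500-600 nm, the deoxy feature near 760 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    MeasurementRecord,
    SpectralDataset,
    Spectrum,
    WavelengthGrid,
    default_instrument_grid,
)

__all__ = [
    "Concentration",
    "FluorophoreBand",
    "ChromophoreBand",
    "TissueClassSpec",
    "InstrumentSpec",
    "SimulationConfig",
    "emission_profile",
    "absorption_profile",
    "simulate_af",
    "simulate_dr",
    "simulate_dataset",
    "DEFAULT_FLUOROPHORE_BANDS",
    "DEFAULT_CHROMOPHORE_BANDS",
]


@dataclass(frozen=True)
class Concentration:
    """Class-level concentration: between-sample lognormal with this
    arithmetic mean and coefficient of variation."""

    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.cv < 0:
            raise ValueError("concentration mean and cv must be non-negative")

    def sample(self, rng: np.random.Generator) -> float:
        if self.mean == 0:
            return 0.0
        if self.cv == 0:
            return self.mean
        sigma = np.sqrt(np.log1p(self.cv**2))
        mu = np.log(self.mean) - sigma**2 / 2  # arithmetic mean == self.mean
        return float(rng.lognormal(mu, sigma))


@dataclass(frozen=True)
class FluorophoreBand:
    """Gaussian emission band of one fluorophore species."""

    name: str
    center_nm: float
    width_nm: float  # Gaussian sd
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")


def emission_profile(band: FluorophoreBand, grid: WavelengthGrid) -> np.ndarray:
    """Gaussian emission, peak value ``band.amplitude`` at ``center_nm``."""
    lo, hi = grid.span()
    if not lo <= band.center_nm <= hi:
        raise ValueError(f"band center {band.center_nm} nm outside grid span [{lo}, {hi}]")
    lam = grid.values
    return band.amplitude * np.exp(-((lam - band.center_nm) ** 2) / (2 * band.width_nm**2))


@dataclass(frozen=True)
class ChromophoreBand:
    """Unit-concentration absorption profile: a sum of Gaussian bands,
    each (center_nm, width_nm, strength)."""

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for _, width, strength in self.bands:
            if width <= 0 or strength < 0:
                raise ValueError("absorption bands need positive width and strength >= 0")


def absorption_profile(chromophore: ChromophoreBand, grid: WavelengthGrid) -> np.ndarray:
    lam = grid.values
    mu = np.zeros_like(lam)
    for center, width, strength in chromophore.bands:
        mu += strength * np.exp(-((lam - center) ** 2) / (2 * width**2))
    return mu


#: Emission bands placed at the wavelengths where AF variance concentrates.
DEFAULT_FLUOROPHORE_BANDS: dict[str, FluorophoreBand] = {
    "collagen": FluorophoreBand("collagen", center_nm=475.0, width_nm=20.0),
    "flavin": FluorophoreBand("flavin", center_nm=550.0, width_nm=20.0),
    "porphyrin": FluorophoreBand("porphyrin", center_nm=650.0, width_nm=15.0),
    "lipofuscin": FluorophoreBand("lipofuscin", center_nm=600.0, width_nm=20.0),
}

#: Oxy-heme Q-bands at 542/576 nm; deoxy band at 556 nm plus the ~760 nm feature.
DEFAULT_CHROMOPHORE_BANDS: dict[str, ChromophoreBand] = {
    "oxy_heme": ChromophoreBand("oxy_heme", ((542.0, 12.0, 0.8), (576.0, 12.0, 1.0))),
    "deoxy_heme": ChromophoreBand("deoxy_heme", ((556.0, 15.0, 1.0), (760.0, 20.0, 0.35))),
}


@dataclass(frozen=True)
class TissueClassSpec:
    """Optical make-up of one tissue class: mean fluorophore and
    chromophore concentrations (with between-sample CVs) and a power-law
    scattering term ``S(lambda) = a (lambda / 500 nm)^-b``."""

    name: str
    fluorophores: dict[str, Concentration] = field(default_factory=dict)
    chromophores: dict[str, Concentration] = field(default_factory=dict)
    scattering_amplitude: float = 1.0
    scattering_exponent: float = 1.0


@dataclass(frozen=True)
class InstrumentSpec:
    """Spectrometer and probe model.

    ``gain_jitter_sd`` is the log-scale sd of the per-acquisition
    multiplicative gain (0.05 ~ 5% CV); ``read_noise_sd`` is additive
    Gaussian detector noise in counts (20 counts = 2% of the default
    1000-count signal scale); ``ambient_level`` is a flat room-light
    background in counts.  The white reference is a smooth lamp-like
    curve rising toward the near-infrared.
    """

    grid: WavelengthGrid = field(default_factory=default_instrument_grid)
    gain_jitter_sd: float = 0.05
    ambient_level: float = 50.0
    read_noise_sd: float = 20.0
    signal_scale: float = 1000.0
    white_center_nm: float = 800.0
    white_width_nm: float = 350.0
    white_amplitude: float = 4000.0

    def __post_init__(self) -> None:
        if self.gain_jitter_sd < 0 or self.read_noise_sd < 0 or self.ambient_level < 0:
            raise ValueError("noise levels must be non-negative")

    def ambient(self) -> np.ndarray:
        return np.full(len(self.grid), self.ambient_level)

    def white_curve(self) -> np.ndarray:
        lam = self.grid.values
        shape = np.exp(-((lam - self.white_center_nm) ** 2) / (2 * self.white_width_nm**2))
        return self.white_amplitude * (0.05 + shape)


@dataclass(frozen=True)
class SimulationConfig:
    classes: tuple[TissueClassSpec, ...]
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    fluorophore_bands: dict[str, FluorophoreBand] = field(
        default_factory=lambda: dict(DEFAULT_FLUOROPHORE_BANDS)
    )
    chromophore_bands: dict[str, ChromophoreBand] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOPHORE_BANDS)
    )
    n_per_class: int = 30
    seed: int = 0
    af_attenuation: bool = True  # chromophores also attenuate AF emission

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _attenuation(
    class_spec: TissueClassSpec,
    chromophore_bands: dict[str, ChromophoreBand],
    grid: WavelengthGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    total_mu = np.zeros(len(grid))
    for name, conc in class_spec.chromophores.items():
        k = conc.sample(rng)
        total_mu += k * absorption_profile(chromophore_bands[name], grid)
    return np.exp(-total_mu)


def _gain(instrument: InstrumentSpec, rng: np.random.Generator) -> float:
    if instrument.gain_jitter_sd == 0:
        return 1.0
    return float(rng.lognormal(0.0, instrument.gain_jitter_sd))


def _read_noise(instrument: InstrumentSpec, rng: np.random.Generator) -> np.ndarray:
    if instrument.read_noise_sd == 0:
        return np.zeros(len(instrument.grid))
    return rng.normal(0.0, instrument.read_noise_sd, size=len(instrument.grid))


def _background(instrument: InstrumentSpec, rng: np.random.Generator) -> Spectrum:
    return Spectrum(instrument.grid, instrument.ambient() + _read_noise(instrument, rng), "raw")


def simulate_af(
    class_spec: TissueClassSpec,
    instrument: InstrumentSpec,
    rng: np.random.Generator,
    fluorophore_bands: dict[str, FluorophoreBand] | None = None,
    chromophore_bands: dict[str, ChromophoreBand] | None = None,
    attenuate: bool = True,
) -> tuple[Spectrum, Spectrum]:
    """One raw AF acquisition plus a matching background acquisition.

    raw = g * signal_scale * sum_f c_f E_f(lambda) * exp(-sum_c k_c mu_c)
          + ambient + read noise
    """
    fbands = fluorophore_bands or DEFAULT_FLUOROPHORE_BANDS
    cbands = chromophore_bands or DEFAULT_CHROMOPHORE_BANDS
    grid = instrument.grid

    emission = np.zeros(len(grid))
    for name, conc in class_spec.fluorophores.items():
        c = conc.sample(rng)
        emission += c * emission_profile(fbands[name], grid)
    atten = _attenuation(class_spec, cbands, grid, rng) if attenuate else 1.0
    raw = (
        _gain(instrument, rng) * instrument.signal_scale * emission * atten
        + instrument.ambient()
        + _read_noise(instrument, rng)
    )
    return Spectrum(grid, raw, "raw"), _background(instrument, rng)


def simulate_dr(
    class_spec: TissueClassSpec,
    instrument: InstrumentSpec,
    rng: np.random.Generator,
    chromophore_bands: dict[str, ChromophoreBand] | None = None,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """One raw DR acquisition plus matching background and white spectra.

    raw = g * W(lambda) * S(lambda) * exp(-sum_c k_c mu_c) + ambient + noise
    white = W(lambda) + ambient + noise
    """
    cbands = chromophore_bands or DEFAULT_CHROMOPHORE_BANDS
    grid = instrument.grid
    lam = grid.values

    scattering = class_spec.scattering_amplitude * (lam / 500.0) ** (
        -class_spec.scattering_exponent
    )
    atten = _attenuation(class_spec, cbands, grid, rng)
    w = instrument.white_curve()
    raw = (
        _gain(instrument, rng) * w * scattering * atten
        + instrument.ambient()
        + _read_noise(instrument, rng)
    )
    white = Spectrum(grid, w + instrument.ambient() + _read_noise(instrument, rng), "raw")
    return Spectrum(grid, raw, "raw"), _background(instrument, rng), white


def simulate_dataset(config: SimulationConfig, modality: str = "AF") -> SpectralDataset:
    """Simulate ``n_per_class`` acquisitions per class as a labeled dataset.

    One shared background (and, for DR, one shared white reference) is
    generated for the whole session, as when references are captured once
    per sitting.  The output is fully determined by ``config.seed`` and is
    writable through :mod:`myospec.io`.
    """
    if modality not in ("AF", "DR"):
        raise ValueError("modality must be 'AF' or 'DR'")
    rng = np.random.default_rng(config.seed)
    instrument = config.instrument

    references: dict[str, Spectrum] = {"BG1": _background(instrument, rng)}
    reference_records = {"BG1": MeasurementRecord("BG1", "BG")}
    white_id = ""
    if modality == "DR":
        white_id = "WHITE1"
        white_raw = Spectrum(
            instrument.grid,
            instrument.white_curve() + instrument.ambient() + _read_noise(instrument, rng),
            "raw",
        )
        references[white_id] = white_raw
        reference_records[white_id] = MeasurementRecord(
            "WHITE1", "WHITE", background_id="BG1"
        )

    rows, labels = [], []
    for class_spec in config.classes:
        for i in range(config.n_per_class):
            if modality == "AF":
                raw, _ = simulate_af(
                    class_spec,
                    instrument,
                    rng,
                    config.fluorophore_bands,
                    config.chromophore_bands,
                    attenuate=config.af_attenuation,
                )
            else:
                raw, _, _ = simulate_dr(class_spec, instrument, rng, config.chromophore_bands)
            rows.append(raw.intensity)
            labels.append(
                MeasurementRecord(
                    measurement_id=f"{modality}_{class_spec.name}_{i + 1:03d}",
                    modality=modality,
                    group=class_spec.name,
                    muscle=class_spec.name,
                    animal_id=f"{class_spec.name}_a{i + 1}",
                    side="NA",
                    replicate=1,
                    background_id="BG1",
                    white_id=white_id,
                )
            )

    dataset = SpectralDataset(
        grid=instrument.grid,
        matrix=np.vstack(rows),
        labels=labels,
        class_field="group",
        references=references,
        reference_records=reference_records,
    )
    dataset.validate()
    return dataset
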