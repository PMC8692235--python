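"""Bundled simulation scenarios and SimulationConfig (de)serialization.

Three study-like scenarios ship as YAML config files:

* ``muscle_types`` — four healthy tissue classes (Quad, Gastr, TA, Heart)
  whose between-sample variation is driven by three fluorophore
  concentration factors (bands at 475/550/650 nm, CV 20%) under a shared,
  fixed heme attenuation.  This is the package's default simulation.
* ``muscle_types_dr`` — the same classes contrasted for diffuse
  reflectance: cardiac muscle carries more deoxy-heme (deepening the
  500-600 nm bands and the ~760 nm feature) and adjusted scattering.
* ``nf1_like`` — control vs an NF1-like myopathy: collagen fluorophore
  +100% (fibrosis) and heme absorption -50% (adipose dilution, a weak
  visible absorber).
* ``dystrophic_aging`` — 3-week vs 10-week dystrophic muscle: the
  lipofuscin band +150% with age.

All magnitudes are synthetic modeling choices (see the YAML comments);
no quantitative optical coefficients exist for these tissue classes.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import yaml

from .simulate import (
    ChromophoreBand,
    Concentration,
    FluorophoreBand,
    InstrumentSpec,
    SimulationConfig,
    TissueClassSpec,
)
from .spectra import WavelengthGrid, default_instrument_grid

__all__ = [
    "simulation_config_to_dict",
    "simulation_config_from_dict",
    "save_simulation_config",
    "load_simulation_config",
    "load_scenario",
    "default_config",
    "null_config",
    "nf1_like_config",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("muscle_types", "muscle_types_dr", "nf1_like", "dystrophic_aging")


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    grid = config.instrument.grid
    values = grid.values
    return {
        "seed": config.seed,
        "n_per_class": config.n_per_class,
        "af_attenuation": config.af_attenuation,
        "instrument": {
            "grid": {
                "n_points": len(grid),
                "lo_nm": float(values[0]),
                "hi_nm": float(values[-1]),
            },
            "gain_jitter_sd": config.instrument.gain_jitter_sd,
            "ambient_level": config.instrument.ambient_level,
            "read_noise_sd": config.instrument.read_noise_sd,
            "signal_scale": config.instrument.signal_scale,
            "white_center_nm": config.instrument.white_center_nm,
            "white_width_nm": config.instrument.white_width_nm,
            "white_amplitude": config.instrument.white_amplitude,
        },
        "fluorophore_bands": {
            name: {"center_nm": b.center_nm, "width_nm": b.width_nm, "amplitude": b.amplitude}
            for name, b in config.fluorophore_bands.items()
        },
        "chromophore_bands": {
            name: {
                "bands": [
                    {"center_nm": c, "width_nm": w, "strength": s} for c, w, s in b.bands
                ]
            }
            for name, b in config.chromophore_bands.items()
        },
        "classes": [
            {
                "name": spec.name,
                "fluorophores": {
                    n: {"mean": c.mean, "cv": c.cv} for n, c in spec.fluorophores.items()
                },
                "chromophores": {
                    n: {"mean": c.mean, "cv": c.cv} for n, c in spec.chromophores.items()
                },
                "scattering_amplitude": spec.scattering_amplitude,
                "scattering_exponent": spec.scattering_exponent,
            }
            for spec in config.classes
        ],
    }


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    grid_spec = d["instrument"]["grid"]
    grid = default_instrument_grid(
        n_points=int(grid_spec["n_points"]),
        lo_nm=float(grid_spec["lo_nm"]),
        hi_nm=float(grid_spec["hi_nm"]),
    )
    inst = d["instrument"]
    instrument = InstrumentSpec(
        grid=grid,
        gain_jitter_sd=float(inst["gain_jitter_sd"]),
        ambient_level=float(inst["ambient_level"]),
        read_noise_sd=float(inst["read_noise_sd"]),
        signal_scale=float(inst["signal_scale"]),
        white_center_nm=float(inst["white_center_nm"]),
        white_width_nm=float(inst["white_width_nm"]),
        white_amplitude=float(inst["white_amplitude"]),
    )
    fbands = {
        name: FluorophoreBand(
            name,
            center_nm=float(b["center_nm"]),
            width_nm=float(b["width_nm"]),
            amplitude=float(b.get("amplitude", 1.0)),
        )
        for name, b in d.get("fluorophore_bands", {}).items()
    }
    cbands = {
        name: ChromophoreBand(
            name,
            tuple(
                (float(x["center_nm"]), float(x["width_nm"]), float(x["strength"]))
                for x in b["bands"]
            ),
        )
        for name, b in d.get("chromophore_bands", {}).items()
    }
    classes = tuple(
        TissueClassSpec(
            name=c["name"],
            fluorophores={
                n: Concentration(float(v["mean"]), float(v.get("cv", 0.0)))
                for n, v in c.get("fluorophores", {}).items()
            },
            chromophores={
                n: Concentration(float(v["mean"]), float(v.get("cv", 0.0)))
                for n, v in c.get("chromophores", {}).items()
            },
            scattering_amplitude=float(c.get("scattering_amplitude", 1.0)),
            scattering_exponent=float(c.get("scattering_exponent", 1.0)),
        )
        for c in d["classes"]
    )
    return SimulationConfig(
        classes=classes,
        instrument=instrument,
        fluorophore_bands=fbands,
        chromophore_bands=cbands,
        n_per_class=int(d.get("n_per_class", 30)),
        seed=int(d.get("seed", 0)),
        af_attenuation=bool(d.get("af_attenuation", True)),
    )


def save_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(simulation_config_to_dict(config), sort_keys=False), encoding="utf-8"
    )


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return simulation_config_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def load_scenario(name: str) -> SimulationConfig:
    """Load one of the bundled scenario configs by name."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; available: {SCENARIO_NAMES}")
    text = resources.files("myospec.scenarios_data").joinpath(f"{name}.yaml").read_text("utf-8")
    return simulation_config_from_dict(yaml.safe_load(text))


def default_config(n_per_class: int = 30, seed: int = 0) -> SimulationConfig:
    """The default simulation: the bundled ``muscle_types`` scenario."""
    config = load_scenario("muscle_types")
    return replace(config, n_per_class=n_per_class, seed=seed)


def null_config(n_per_class: int = 50, seed: int = 0) -> SimulationConfig:
    """Two classes with identical optical make-up — the no-signal control.

    Any downstream classifier should sit at chance (AUC ~ 0.5) on data
    from this config.
    """
    config = load_scenario("muscle_types")
    quad = next(c for c in config.classes if c.name == "Quad")
    return replace(
        config,
        classes=(replace(quad, name="A"), replace(quad, name="B")),
        n_per_class=n_per_class,
        seed=seed,
    )


def nf1_like_config(
    separation: float = 1.0, n_per_class: int = 30, seed: int = 0
) -> SimulationConfig:
    """The ``nf1_like`` scenario at an adjustable separation level.

    ``separation`` linearly scales the control-to-disease contrast:
    collagen mean ``* (1 + separation)`` and heme means ``* (1 - 0.5 *
    separation)`` relative to the control class.  ``separation=1`` is the
    bundled contrast; ``0`` collapses both classes onto the control.
    """
    if not 0 <= separation <= 1:
        raise ValueError("separation must be in [0, 1]")
    config = load_scenario("nf1_like")
    control = next(c for c in config.classes if c.name == "control")
    disease = next(c for c in config.classes if c.name != "control")

    fluor = dict(control.fluorophores)
    base_coll = fluor["collagen"]
    fluor["collagen"] = Concentration(base_coll.mean * (1.0 + separation), base_coll.cv)
    chrom = {
        n: Concentration(c.mean * (1.0 - 0.5 * separation), c.cv)
        for n, c in control.chromophores.items()
    }
    scaled = TissueClassSpec(
        name=disease.name,
        fluorophores=fluor,
        chromophores=chrom,
        scattering_amplitude=control.scattering_amplitude,
        scattering_exponent=control.scattering_exponent,
    )
    return replace(
        config, classes=(control, scaled), n_per_class=n_per_class, seed=seed
    )
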