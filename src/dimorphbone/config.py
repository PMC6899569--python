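"""Fixture configuration: YAML specs for the ground-truthed phantoms.

Named fixtures (``ct_wt_female``, ``ct_wt_male``, ``ct_ko_male``,
``raman_female``, ``raman_male``) ship with the package; arbitrary YAML
paths are accepted too. Seeds recorded in the YAML can be overridden at
load time so reruns under a different master seed stay reproducible.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .phantom.cortex import (CanalPopulation, CortexPhantomSpec, IntensityModel,
                             LacunaPopulation, OsteoidHalo, SpeckPopulation,
                             TargetComposition)
from .phantom.raman import RamanBand, RamanPhantomSpec

__all__ = ["fixture_path", "load_yaml", "load_cortex_fixture",
           "load_raman_fixture", "CT_FIXTURES", "RAMAN_FIXTURES"]

CT_FIXTURES = ("ct_wt_female", "ct_wt_male", "ct_ko_male")
RAMAN_FIXTURES = ("raman_female", "raman_male")


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture YAML (name without extension) or a file path."""
    p = Path(name)
    if p.suffix in (".yaml", ".yml") and p.exists():
        return p
    return Path(resources.files("dimorphbone") / "fixtures" / f"{name}.yaml")


def load_yaml(name: str) -> dict:
    with open(fixture_path(name)) as fh:
        return yaml.safe_load(fh)


def load_cortex_fixture(name: str, seed: int | None = None,
                        **overrides) -> CortexPhantomSpec:
    """Build a CortexPhantomSpec from a fixture YAML.

    ``overrides`` replace top-level scalar fields (e.g. ``length_slices``)
    or nested population counts via ``lacuna_count``; used to run the same
    composition at a reduced problem size.
    """
    cfg = load_yaml(name)
    if cfg.get("kind") != "cortex_phantom":
        raise ValueError(f"{name} is not a cortex_phantom fixture")
    lac = LacunaPopulation(**cfg.get("lacunae", {}))
    can = CanalPopulation(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in cfg.get("canals", {}).items()})
    spk = SpeckPopulation(**cfg.get("specks", {}))
    halo = OsteoidHalo(**cfg.get("osteoid_halo", {}))
    inten = IntensityModel(**cfg.get("intensity", {}))
    tc = cfg.get("target_composition")
    spec = CortexPhantomSpec(
        outer_radius_um=cfg["outer_radius_um"],
        inner_radius_um=cfg["inner_radius_um"],
        length_slices=cfg["length_slices"],
        voxel_size_um=cfg["voxel_size_um"],
        lacunae=lac, canals=can, specks=spk,
        osteoid_halo=halo, intensity=inten,
        target_composition=TargetComposition(**tc) if tc else None,
        seed=cfg.get("seed", 0) if seed is None else seed,
    )
    if "lacuna_count" in overrides:
        spec.lacunae.count = overrides.pop("lacuna_count")
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise KeyError(f"unknown override {key!r}")
        setattr(spec, key, value)
    return spec


def _bands_from(cfg: dict) -> list[RamanBand]:
    out = []
    for name, b in cfg.items():
        out.append(RamanBand(name=name, center_cm1=b["center"], area=b["area"],
                             sigma_cm1=b.get("sigma", 3.0),
                             gaussian_fraction=b.get("gaussian_fraction", 0.7)))
    return out


def load_raman_fixture(name: str, seed: int | None = None,
                       n_spectra: int | None = None) -> dict:
    """Build per-group RamanPhantomSpec objects plus the fixture's true folds.

    Returns ``{"groups": {group: spec}, "true_folds": {...}}``; group seeds
    are derived from the fixture (or overriding) seed.
    """
    cfg = load_yaml(name)
    if cfg.get("kind") != "raman_phantom":
        raise ValueError(f"{name} is not a raman_phantom fixture")
    base_seed = cfg.get("seed", 0) if seed is None else seed
    shared = cfg.get("shared_bands", {})
    groups = {}
    for gi, (group, gcfg) in enumerate(cfg["groups"].items()):
        bands = _bands_from({**shared, **gcfg["bands"]})
        groups[group] = RamanPhantomSpec(
            bands=bands,
            baseline_coeffs=cfg.get("baseline_coeffs", [0.0]),
            noise_sigma_rel=cfg.get("noise_sigma_rel", 0.01),
            area_jitter_cv=cfg.get("area_jitter_cv", 0.05),
            cosmic_spike_count=cfg.get("cosmic_spike_count", 0),
            n_spectra=n_spectra or cfg.get("n_spectra_per_group", 50),
            wavenumber_step_cm1=cfg.get("wavenumber_step_cm1", 0.5),
            seed=(base_seed * 7919 + gi) % (2 ** 31),
        )
    return {"groups": groups, "true_folds": dict(cfg.get("true_folds", {}))}
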