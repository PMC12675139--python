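"""Run configuration: one structured file describing a whole experiment.

A run is a grid of cells, a base climatology with a latitudinal temperature
gradient, named scenarios expressed as deltas on that climatology, an
ensemble size, the crop/soil/management parameter sets and the aggregation
thresholds.  ``validate_config`` reports every violated invariant with its
field path instead of stopping at the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import ManagementConfig, SoilProfile
from .phenology import CropParameters, SowingRule
from .weather import ClimateSpec

__all__ = ["RunConfig", "load_config", "validate_config"]


@dataclass
class RunConfig:
    seed: int = 0
    start_year: int = 1985
    n_years: int = 30
    n_members: int = 5
    cells: list[tuple[float, float]] = field(
        default_factory=lambda: [(46.25, 5.25), (48.25, 9.25), (50.25, 13.25), (52.25, 17.25)]
    )
    climate: dict = field(default_factory=dict)  # base ClimateSpec overrides
    ref_lat: float = 48.0
    temp_lat_gradient: float = -0.6  # degC per degree latitude north of ref_lat
    scenarios: dict[str, dict] = field(
        default_factory=lambda: {"baseline": {}, "warm2": {"delta_T": 2.0}}
    )
    crop: CropParameters = field(default_factory=CropParameters)
    soil: SoilProfile = field(default_factory=SoilProfile)
    sowing: SowingRule = field(default_factory=SowingRule)
    fertility_stress: float = 30.0
    irrigation_trigger_fraction: float = 0.5
    min_years: int = 5
    unsuitable_below: float = 4.0
    profitable_above: float = 7.0
    elevation: float = 0.0
    output_dir: str | None = None

    def cell_spec(self, cell_index: int, scenario: str) -> ClimateSpec:
        """ClimateSpec for one cell under one scenario.

        The cell seed derives deterministically from the global seed and the
        cell index only (not the scenario), so paired scenarios share their
        underlying weather noise and differ exactly by the scenario deltas.
        """
        lat, _lon = self.cells[cell_index]
        fields = dict(self.climate)
        base_mean = fields.get("annual_mean_temp", ClimateSpec.annual_mean_temp)
        fields["annual_mean_temp"] = base_mean + self.temp_lat_gradient * (lat - self.ref_lat)
        fields["latitude"] = lat
        fields.update(self.scenarios[scenario])
        seed = int(
            np.random.SeedSequence([int(self.seed), cell_index]).generate_state(1)[0]
            % 2**31
        )
        return ClimateSpec(seed=seed, **fields)

    def management(self, regime: str) -> ManagementConfig:
        trig = self.irrigation_trigger_fraction
        if regime == "ya":
            return ManagementConfig(self.fertility_stress, "off", trig)
        if regime == "yw":
            return ManagementConfig(0.0, "off", trig)
        if regime == "yp":
            return ManagementConfig(0.0, "net-requirement", trig)
        raise ValueError(f"unknown regime {regime!r}")


_SECTION_TYPES = {
    "crop": CropParameters,
    "soil": SoilProfile,
    "sowing": SowingRule,
}


def _build(raw: dict) -> RunConfig:
    kwargs = dict(raw)
    for name, cls in _SECTION_TYPES.items():
        if name in kwargs and isinstance(kwargs[name], dict):
            section = dict(kwargs[name])
            if name == "sowing":
                for key in ("window_start", "window_end"):
                    if key in section and isinstance(section[key], (list, tuple)):
                        section[key] = tuple(section[key])
            kwargs[name] = cls(**section)
    if "cells" in kwargs:
        kwargs["cells"] = [tuple(c) for c in kwargs["cells"]]
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    cfg = _build(raw)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Return every violated invariant as a "field.path: message" line."""
    problems: list[str] = []

    def check(path: str, fn) -> None:
        try:
            fn()
        except (ValueError, TypeError) as exc:
            problems.append(f"{path}: {exc}")

    check("crop", lambda: dataclasses.replace(cfg.crop))
    check("soil", lambda: dataclasses.replace(cfg.soil))
    check("sowing", lambda: dataclasses.replace(cfg.sowing))
    check(
        "management",
        lambda: ManagementConfig(
            cfg.fertility_stress, "off", cfg.irrigation_trigger_fraction
        ),
    )
    if cfg.n_years < 1:
        problems.append("n_years: must be >= 1")
    if cfg.n_members < 1:
        problems.append("n_members: must be >= 1")
    if cfg.min_years < 0:
        problems.append("min_years: must be >= 0")
    if not cfg.cells:
        problems.append("cells: at least one grid cell required")
    if cfg.unsuitable_below > cfg.profitable_above:
        problems.append("classification: unsuitable_below exceeds profitable_above")
    if "baseline" not in cfg.scenarios:
        problems.append("scenarios: a 'baseline' scenario is required")
    for name in cfg.scenarios:
        for i in range(len(cfg.cells)):
            try:
                cfg.cell_spec(i, name)
            except ValueError as exc:
                problems.append(f"scenarios.{name}.cell[{i}]: {exc}")
            break  # the spec invariants do not depend on the cell beyond latitude sign
    return problems


def write_manifest(cfg: RunConfig, path: Path, extra: dict | None = None) -> dict:
    """Machine-readable record of what produced a set of outputs."""
    import hashlib
    import json

    payload = dataclasses.asdict(cfg)
    blob = json.dumps(payload, sort_keys=True, default=str)
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "periods": {
            "start_year": cfg.start_year,
            "n_years": cfg.n_years,
        },
    }
    if extra:
        manifest.update(extra)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
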