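"""Run configuration: YAML schema, validation and round-trip rendering.

A config file mirrors the three parameter groups of the model — compound,
biofilm and bed — plus an optional ``run`` section with solver and
schedule settings, so literature parameter tables can be transcribed
section by section::

    compound:
      henry_dimensionless: 0.23
      mu_max_per_hour: 0.68        # or mu_max (s^-1)
      monod_K: 12.22
      yield_Y: 0.708
      diffusivity_water: 1.04e-9
    biofilm:
      density_Xv: 100.0
      area_As: 40.0
      thickness_delta: 5.0e-5
    bed:
      height_H: 1.5
      n_segments: 10
      void_fraction_eps: 0.35
      ebrt: 60.0                   # or superficial_velocity_ug
      inlet_conc_Cg0: 0.13
    run:
      solver: oracle               # analytic | oracle
      seed: 1
      t_end_s: 2000.0
      dt_out_s: null
      ebrt_sweep: [60, 78, 84, 90, 120, 186]

Unknown keys anywhere are errors; ``parse_config(render_config(cfg))``
reproduces ``cfg`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fixtures import benzene_bed, benzene_biofilm, benzene_compound
from .parameters import BedOperation, BiofilmParameters, CompoundParameters

__all__ = ["RunConfig", "parse_config", "render_config", "default_config"]

_COMPOUND_KEYS = {"henry_dimensionless", "mu_max", "mu_max_per_hour", "monod_K", "yield_Y",
                  "diffusivity_water"}
_BIOFILM_KEYS = {"density_Xv", "area_As", "thickness_delta"}
_BED_KEYS = {"height_H", "n_segments", "void_fraction_eps", "superficial_velocity_ug", "ebrt",
             "inlet_conc_Cg0"}
_RUN_KEYS = {"solver", "seed", "t_end_s", "dt_out_s", "ebrt_sweep"}
_SECTIONS = {"compound", "biofilm", "bed", "run"}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}; allowed: {sorted(allowed)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; raw sections are kept for lossless
    round-tripping, typed accessors build the model objects."""

    compound_raw: dict
    biofilm_raw: dict
    bed_raw: dict
    run_raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_keys("compound", self.compound_raw, _COMPOUND_KEYS)
        _check_keys("biofilm", self.biofilm_raw, _BIOFILM_KEYS)
        _check_keys("bed", self.bed_raw, _BED_KEYS)
        _check_keys("run", self.run_raw, _RUN_KEYS)
        if ("mu_max" in self.compound_raw) == ("mu_max_per_hour" in self.compound_raw):
            raise ValueError("[compound] needs exactly one of mu_max (s^-1) or mu_max_per_hour")
        solver = self.run_raw.get("solver", "oracle")
        if solver not in ("analytic", "oracle"):
            raise ValueError(f"run.solver must be 'analytic' or 'oracle', got {solver!r}")
        # construct eagerly so invalid values fail at parse time
        self.compound, self.biofilm, self.bed

    @property
    def compound(self) -> CompoundParameters:
        raw = dict(self.compound_raw)
        if "mu_max_per_hour" in raw:
            return CompoundParameters.with_mu_max_per_hour(**raw)
        return CompoundParameters(**raw)

    @property
    def biofilm(self) -> BiofilmParameters:
        return BiofilmParameters(**self.biofilm_raw)

    @property
    def bed(self) -> BedOperation:
        return BedOperation(**self.bed_raw)

    @property
    def solver(self) -> str:
        return self.run_raw.get("solver", "oracle")

    @property
    def seed(self) -> int | None:
        return self.run_raw.get("seed")

    @property
    def t_end_s(self) -> float:
        return float(self.run_raw.get("t_end_s", 2000.0))

    @property
    def dt_out_s(self) -> float | None:
        v = self.run_raw.get("dt_out_s")
        return None if v is None else float(v)

    @property
    def ebrt_sweep(self) -> list[float] | None:
        v = self.run_raw.get("ebrt_sweep")
        return None if v is None else [float(x) for x in v]

    def replace_bed(self, **updates) -> "RunConfig":
        bed_raw = {**self.bed_raw, **{k: v for k, v in updates.items() if v is not None}}
        return RunConfig(self.compound_raw, self.biofilm_raw, bed_raw, self.run_raw)


def parse_config(source: str | Path) -> RunConfig:
    """Parse a YAML config from a path or a YAML string."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    _check_keys("<root>", data, _SECTIONS)
    for section in ("compound", "biofilm", "bed"):
        if section not in data:
            raise ValueError(f"config is missing required section [{section}]")
    return RunConfig(
        compound_raw=dict(data["compound"]),
        biofilm_raw=dict(data["biofilm"]),
        bed_raw=dict(data["bed"]),
        run_raw=dict(data.get("run", {})),
    )


def render_config(config: RunConfig) -> str:
    """Serialize back to YAML; inverse of :func:`parse_config`."""
    data = {
        "compound": dict(config.compound_raw),
        "biofilm": dict(config.biofilm_raw),
        "bed": dict(config.bed_raw),
    }
    if config.run_raw:
        data["run"] = dict(config.run_raw)
    return yaml.safe_dump(data, sort_keys=False)


def default_config() -> RunConfig:
    """Bundled benzene base case (EBRT 60 s, inlet 0.13 g·m⁻³, n = 10)."""
    c = benzene_compound()
    b = benzene_biofilm()
    bed = benzene_bed()
    return RunConfig(
        compound_raw={
            "henry_dimensionless": c.henry_dimensionless,
            "mu_max_per_hour": 0.68,
            "monod_K": c.monod_K,
            "yield_Y": c.yield_Y,
            "diffusivity_water": c.diffusivity_water,
        },
        biofilm_raw={
            "density_Xv": b.density_Xv,
            "area_As": b.area_As,
            "thickness_delta": b.thickness_delta,
        },
        bed_raw={
            "height_H": bed.height_H,
            "n_segments": bed.n_segments,
            "void_fraction_eps": bed.void_fraction_eps,
            "ebrt": bed.ebrt,
            "inlet_conc_Cg0": bed.inlet_conc_Cg0,
        },
    )
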