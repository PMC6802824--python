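"""Run configuration: parameter tables, band plan and community presets.

The shipped default configuration mirrors the survey's echosounder band
plan, the scattering-model parameter tables for the three scatterer
classes, the uncertainty priors, and the sampled surface/deep community
tables. Any YAML file with the same structure can override it.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .echogram import Band, TransducerBands, default_frequency_grid
from .elastic_shell import ElasticShellParams
from .fluid_like import FluidLikeParams
from .gas_bearing import GasBearingParams
from .medium import Medium
from .uncertainty import ParamDistribution


def _default_text() -> str:
    return (importlib.resources.files("sslforward") / "data" /
            "default.yaml").read_text()


@dataclass
class RunConfig:
    """Validated view over the configuration mapping."""

    raw: dict

    # ------------------------------------------------------------------
    @classmethod
    def load(cls, path: str | None = None) -> "RunConfig":
        text = open(path).read() if path else _default_text()
        cfg = cls(yaml.safe_load(text))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for taxon, entry in self.raw["taxon_map"].items():
            mc = entry["model_class"]
            if mc == "excluded":
                continue
            group = entry.get("group")
            section = {"fluid_like_cylinder": "fluid_like",
                       "fluid_like_spheroid": "fluid_like",
                       "elastic_shell": "elastic_shell",
                       "gas_bearing": "gas_bearing"}.get(mc)
            if section is None:
                raise ValueError(f"taxon {taxon!r}: unknown model class {mc!r}")
            if group not in self.raw.get(section, {}):
                raise ValueError(
                    f"taxon {taxon!r}: parameter group {group!r} missing "
                    f"from section {section!r}")

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    # ------------------------------------------------------------------
    def medium(self, depth_m: float = 0.0) -> Medium:
        m = self.raw["medium"]
        return Medium(m["sound_speed"], m["density"], depth_m,
                      m.get("temperature", 283.15))

    @property
    def bin_width_mm(self) -> float:
        return float(self.raw.get("bin_width_mm", 0.1))

    def bands(self) -> TransducerBands:
        bands = [Band(b["name"], b["f_min"], b["f_max"], b.get("kind", "FM"),
                      b.get("use_in_clustering", True))
                 for b in self.raw["bands"]]
        excl = [tuple(e) for e in self.raw.get("exclusions", [])]
        return TransducerBands(bands, excl)

    def frequency_grid(self, step_khz: float = 2.0) -> np.ndarray:
        return default_frequency_grid(self.bands(), step_khz)

    # ------------------------------------------------------------------
    def model_class_for(self, taxon: str) -> str:
        entry = self._taxon_entry(taxon)
        mc = entry["model_class"]
        if mc == "fluid_like_cylinder" and taxon == "fish_no_swimbladder" \
                and self.raw.get("fish_no_swimbladder_as_gas_bearing"):
            return "gas_bearing"
        return mc

    def length_kind_for(self, taxon: str) -> str:
        return self._taxon_entry(taxon).get("length_kind", "gas_inclusion")

    def _taxon_entry(self, taxon: str) -> dict:
        try:
            return self.raw["taxon_map"][taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in taxon_map") from None

    def params_for(self, taxon: str, model_class: str):
        """Scattering parameter object for a taxon; raises ``KeyError`` for
        unknown taxa and ``ValueError`` on a class mismatch."""
        entry = self._taxon_entry(taxon)
        expected = self.model_class_for(taxon)
        if model_class != expected:
            raise ValueError(
                f"taxon {taxon!r} is configured as {expected!r}, "
                f"records say {model_class!r}")
        group = entry["group"]
        if model_class in ("fluid_like_cylinder", "fluid_like_spheroid"):
            p = self.raw["fluid_like"][group]
            return FluidLikeParams(
                g=p["g"], h=p["h"],
                length_to_radius_ratio=2.0 * p["length_to_width_ratio"],
                orientation_mean_deg=p["orientation_mean"],
                orientation_sd_deg=p["orientation_sd"],
                shape=p["shape"])
        if model_class == "elastic_shell":
            p = self.raw["elastic_shell"][group]
            return ElasticShellParams(p["reflection_coefficient"])
        if model_class == "gas_bearing":
            if taxon == "fish_no_swimbladder":
                group = "other_fish"
            p = self.raw["gas_bearing"][group]
            return GasBearingParams(p["length_to_width_ratio"],
                                    p["viscosity"], p["surface_tension"])
        raise ValueError(f"cannot build parameters for class {model_class!r}")

    def resolver(self):
        """A ``param_resolver`` callable for :func:`forward.predict_layer`."""
        return self.params_for

    # ------------------------------------------------------------------
    def priors_for(self, group: str) -> list[ParamDistribution]:
        try:
            block = self.raw["priors"][group]
        except KeyError:
            raise KeyError(f"no priors for group {group!r}") from None
        return [ParamDistribution(name, d["kind"], float(d["mu"]),
                                  float(d["sd"]))
                for name, d in block.items()]

    def layer_names(self) -> list[str]:
        return list(self.raw.get("layers", {}))

    def layer_block(self, name: str) -> dict:
        try:
            return self.raw["layers"][name]
        except KeyError:
            raise KeyError(f"no layer preset named {name!r}") from None

    def layer_depth_midpoint(self, name: str) -> float:
        block = self.layer_block(name)
        return 0.5 * (block["depth_min_m"] + block["depth_max_m"])


def load_config(path: str | None = None) -> RunConfig:
    return RunConfig.load(path)
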