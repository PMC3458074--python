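"""Run configuration for the full analysis chain.

Each correction regime of the analysis has its own (per-voxel p, extent
cutoff) pair; defaults follow the emulated study: within-group seed maps
at p<0.001 with clusters >14 voxels, between-group maps at p<0.001 with
clusters >10 voxels inside the combined within-group mask, within-group
asymmetry at p<0.001 / >10 voxels, and between-group asymmetry at p<0.01
/ >13 voxels inside the explicit asymmetry mask.  Extents are strict
lower bounds (a cluster must exceed the cutoff to survive).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .preprocess import CleaningSpec
from .synth import SimulationConfig

__all__ = ["CorrectionRegime", "RunConfig"]


@dataclass
class CorrectionRegime:
    voxel_p: float
    min_extent: int  # clusters must have extent strictly greater than this

    def validate(self) -> None:
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if self.min_extent < 1:
            raise ValueError("min_extent must be >= 1")


@dataclass
class RunConfig:
    """All parameters of a full synthetic-study analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cleaning: CleaningSpec = field(default_factory=CleaningSpec)
    within_group: CorrectionRegime = field(
        default_factory=lambda: CorrectionRegime(0.001, 14))
    between_group: CorrectionRegime = field(
        default_factory=lambda: CorrectionRegime(0.001, 10))
    asymmetry_within: CorrectionRegime = field(
        default_factory=lambda: CorrectionRegime(0.001, 10))
    asymmetry_between: CorrectionRegime = field(
        default_factory=lambda: CorrectionRegime(0.01, 13))
    connectivity: str = "faces"
    fwhm_mm: float = 6.0
    n_null_iter: int = 2000
    sphere_radius_mm: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        self.cleaning.validate()
        for regime in (self.within_group, self.between_group,
                       self.asymmetry_within, self.asymmetry_between):
            regime.validate()

    # -- (de)serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        # tuples -> lists for clean YAML
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        from .synth import CouplingSpec, PlantedCorrelation

        kwargs = dict(payload)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            if "grid_dims" in sim:
                sim["grid_dims"] = tuple(sim["grid_dims"])
            if "couplings" in sim:
                sim["couplings"] = [CouplingSpec(**c) for c in sim["couplings"]]
            if "behavior_correlations" in sim:
                sim["behavior_correlations"] = [
                    PlantedCorrelation(**p) for p in sim["behavior_correlations"]]
            kwargs["simulation"] = SimulationConfig(**sim)
        if "cleaning" in kwargs:
            clean = dict(kwargs["cleaning"])
            if clean.get("band_hz") is not None:
                clean["band_hz"] = tuple(clean["band_hz"])
            kwargs["cleaning"] = CleaningSpec(**clean)
        for key in ("within_group", "between_group",
                    "asymmetry_within", "asymmetry_between"):
            if key in kwargs:
                kwargs[key] = CorrectionRegime(**kwargs[key])
        return cls(**kwargs)


def _plain(obj):
    """Recursively convert tuples to lists for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
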