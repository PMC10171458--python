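"""Serializable pipeline configuration.

One YAML document drives the whole pipeline: acquisition scheme, noise,
fit settings, ROI sizing, pathology linkage and statistics options, plus
the single root seed every random stream descends from. Defaults equal the
documented per-module defaults, and serialize -> parse -> serialize is a
fixed point.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .scheme import BValueScheme, DEFAULT_B_VALUES, default_nex
from .sem_fit import FitSettings
from .synthetic_data import LinkageParams


@dataclass(frozen=True)
class PipelineConfig:
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    nex: tuple[int, ...] | None = None            # None -> schedule by b
    sigma0: float = 0.0
    phantom_shape: tuple[int, int, int] = (64, 64, 8)
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 4.0)
    fit: FitSettings = field(default_factory=FitSettings)
    roi_area_mm2: float = 105.0
    n_readers: int = 2
    reader_jitter_sd: dict[str, float] = field(
        default_factory=lambda: {"ddc1500": 2e-5, "alpha1500": 0.01,
                                 "ddc5000": 2e-5, "alpha5000": 0.01}
    )
    link: LinkageParams = field(default_factory=LinkageParams)
    n_specimens: int = 32
    n_patients: int = 21
    n_missing_mib1: int = 1
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    seed: int = 0

    def scheme(self) -> BValueScheme:
        b = np.array(self.b_values, dtype=float)
        nex = (np.array(self.nex, dtype=int) if self.nex is not None
               else np.array([default_nex(bi) for bi in b]))
        return BValueScheme(b, nex)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["b_values"] = [float(b) for b in self.b_values]
        d["nex"] = None if self.nex is None else [int(n) for n in self.nex]
        d["phantom_shape"] = list(self.phantom_shape)
        d["voxel_size"] = list(self.voxel_size)
        d["alpha_levels"] = list(self.alpha_levels)
        d["fit"]["ddc_bounds"] = list(self.fit.ddc_bounds)
        d["fit"]["alpha_bounds"] = list(self.fit.alpha_bounds)
        d["link"]["grade_thresholds"] = list(self.link.grade_thresholds)
        d["link"]["n_fields_range"] = list(self.link.n_fields_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fit = d.pop("fit", {})
        link = d.pop("link", {})
        for key in ("ddc_bounds", "alpha_bounds"):
            if key in fit:
                fit[key] = tuple(fit[key])
        for key in ("grade_thresholds", "n_fields_range"):
            if key in link:
                link[key] = tuple(link[key])
        for key in ("b_values", "phantom_shape", "voxel_size", "alpha_levels", "nex"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(fit=FitSettings(**fit), link=LinkageParams(**link), **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def digest(self) -> str:
        """Stable hash of the serialized config, for run logs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
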