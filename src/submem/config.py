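"""Pipeline configuration: schema, defaults, YAML round-trip, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .designmat import ENCODING_MODELS, HRFParams
from .synthdata import AcquisitionSpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Validated configuration for the full analysis pipeline."""

    seed: int = 1
    n_subjects: int = 4
    out_dir: str = "submem_out"
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    hrf: HRFParams = field(default_factory=HRFParams)
    generative_model: str = "decay"
    analysis_model: str = "sample_plus_delay"
    ppc_models: tuple[str, ...] = ENCODING_MODELS
    gamma0: float = 2.0
    gamma1: float = 0.5
    noise_sd: float = 1.0
    alpha: float = 0.01
    n_permutations: int = 199
    permutation_scheme: str = "global"
    connectivity: int = 26
    roi_radius: float = 5.0
    ppc_n_sim: int = 20

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 for the group model")
        for name in ("generative_model", "analysis_model"):
            if getattr(self, name) not in ENCODING_MODELS:
                raise ValueError(f"{name} must be one of {ENCODING_MODELS}")
        for m in self.ppc_models:
            if m not in ENCODING_MODELS:
                raise ValueError(f"unknown PPC model {m!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if self.permutation_scheme not in ("global", "within_subject"):
            raise ValueError("permutation_scheme must be 'global' or 'within_subject'")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be positive")
        if self.ppc_n_sim < 1:
            raise ValueError("ppc_n_sim must be >= 1")
        self.hrf.validate()
        self.acquisition.validate_schedule_arithmetic()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ppc_models"] = list(self.ppc_models)
        d["acquisition"]["grid_shape"] = list(self.acquisition.grid_shape)
        d["acquisition"]["itis"] = list(self.acquisition.itis)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "acquisition" in d and not isinstance(d["acquisition"], AcquisitionSpec):
            acq = dict(d["acquisition"])
            for key in ("grid_shape", "itis"):
                if key in acq:
                    acq[key] = tuple(acq[key])
            d["acquisition"] = AcquisitionSpec(**acq)
        if "hrf" in d and not isinstance(d["hrf"], HRFParams):
            d["hrf"] = HRFParams(**d["hrf"])
        if "ppc_models" in d:
            d["ppc_models"] = tuple(d["ppc_models"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config (or defaults) with keyword overrides applied."""
    d = {}
    if path is not None:
        d = yaml.safe_load(Path(path).read_text()) or {}
    d.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig.from_dict(d)
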