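"""Pipeline configuration: YAML-backed settings with validation.

Defaults mirror the characterization study's acquisition and analysis
settings: TR 0.5 s, 1 s stimulus, 40.5 s inter-stimulus interval, 1000
volumes over 6 axial slices; highpass cutoff 50 s; spatial smoothing FWHM
5 mm; cluster-forming z 2.3 with corrected alpha 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # acquisition
    tr: float = 0.5
    n_volumes: int = 1000
    shape: tuple[int, int, int] = (32, 32, 6)
    voxel_sizes: tuple[float, float, float] = (3.125, 3.125, 4.0)
    # event design
    stim_duration: float = 1.0
    isi: float = 40.5
    # block design (for the HRF-application stage)
    block_tr: float = 1.0
    block_n_volumes: int = 240
    block_on: float = 24.0
    block_off: float = 24.0
    # synthesis
    groups: tuple[str, ...] = ("adult",)
    n_subjects: int = 3
    truth_amplitude: float | None = None  # None -> the group preset amplitude
    noise_sd: float = 10.0
    active_radius: float = 2.0
    # preprocessing
    highpass_cutoff: float = 50.0
    smooth_fwhm: float = 5.0
    # GLM / inference
    z_thresh: float = 2.3
    alpha: float = 0.05
    n_permutations: int = 199
    ar_order: int = 1
    basis_k: int = 3
    basis_n_samples: int = 500
    # fitting
    start_ttps: tuple[float, ...] = (4.0, 6.0, 8.0, 11.0, 14.0)
    # CBF
    target_cbf: float = 21.0
    brain_volume: float = 400.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "tr": self.tr, "n_volumes": self.n_volumes,
            "stim_duration": self.stim_duration,
            "highpass_cutoff": self.highpass_cutoff,
            "z_thresh": self.z_thresh, "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "target_cbf": self.target_cbf, "brain_volume": self.brain_volume,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"config field {name} must be positive, got {value}")
        if self.smooth_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("smooth_fwhm and noise_sd must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")
        unknown = set(self.groups) - {"preterm", "term", "adult"}
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        self.shape = tuple(int(x) for x in self.shape)
        self.voxel_sizes = tuple(float(x) for x in self.voxel_sizes)
        self.groups = tuple(self.groups)
        self.start_ttps = tuple(float(x) for x in self.start_ttps)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (all fields optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    data.update(overrides)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**data)
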