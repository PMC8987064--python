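"""Declarative pipeline configuration.

Every analysis constant is a config default, never hard-coded at use sites:
the 0.1 s experimental frame interval, the 0.005 FRET bin-width floor, the
1..1000 decay-fit lag range, 200-frame correlation windows, the 10x0.1 GLCM
quantization, the 0.8 correlation threshold, the catalytic motif and
hemopexin domain range (author numbering), and the 10% top-two-mode
affinity gap.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sampling_interval_s: float = 0.1
    fret_bin_width: float = 0.005
    correlation_fit_min_lag: int = 1
    correlation_fit_max_lag: int = 1000
    window_frames: int = 200
    glcm_bins: int = 10
    glcm_bin_width: float = 0.1
    correlation_threshold: float = 0.8
    catalytic_motif_residues: tuple[int, ...] = tuple(range(218, 229))
    origin_residue_id: int = 219
    hemopexin_range: tuple[int, int] = (279, 466)
    affinity_gap_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "sampling_interval_s": self.sampling_interval_s,
            "fret_bin_width": self.fret_bin_width,
            "correlation_fit_min_lag": self.correlation_fit_min_lag,
            "correlation_fit_max_lag": self.correlation_fit_max_lag,
            "window_frames": self.window_frames,
            "glcm_bins": self.glcm_bins,
            "glcm_bin_width": self.glcm_bin_width,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.correlation_fit_min_lag >= self.correlation_fit_max_lag:
            raise ValueError("correlation_fit_min_lag must be < fit_max_lag")
        if abs(self.glcm_bins * self.glcm_bin_width - 1.0) > 1e-9:
            raise ValueError(
                "glcm_bins * glcm_bin_width must equal 1 (normalized "
                f"correlations live in [0, 1]); got "
                f"{self.glcm_bins} * {self.glcm_bin_width}")
        if self.origin_residue_id not in self.catalytic_motif_residues:
            raise ValueError("origin residue must be in the catalytic motif")

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["catalytic_motif_residues"] = list(self.catalytic_motif_residues)
        d["hemopexin_range"] = list(self.hemopexin_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "catalytic_motif_residues" in data:
            data["catalytic_motif_residues"] = tuple(
                data["catalytic_motif_residues"])
        if "hemopexin_range" in data:
            data["hemopexin_range"] = tuple(data["hemopexin_range"])
        return cls(**data)

    def hash(self) -> str:
        """Stable content hash for run logs."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
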