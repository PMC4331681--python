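"""Run configuration: defaults, YAML loading, and the config echo."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .rotations import (
    DEFAULT_N_THETA,
    DEFAULT_ROTATION_STEP,
    RotationSet,
    default_rotation_set,
    import_rotations,
)
from .voxelizer import ScoreParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Complete, serializable configuration of one docking run.

    The resolved config is echoed verbatim into every result (TSV header and
    :class:`~fftdock.fft_search.DockingResult`), so a rerun from the echo
    reproduces the result bit-identically.
    """

    # grid geometry
    pitch: float = 1.2  # Å per voxel; yields N ≈ 128 for typical pairs
    margin: int = 1  # extra voxels around the receptor per side

    # rotational sampling
    rotation_step: float = DEFAULT_ROTATION_STEP  # degrees
    rotation_file: str | None = None  # external 3-column angle set, overrides step
    n_theta_cap: int | None = DEFAULT_N_THETA

    # score-model constants (see voxelizer.ScoreParams)
    surface_value: float = 1.0
    core_value: float = -45.0
    surface_thickness: int = 2
    elec_clamp: float = 10.0
    desolv_cap: int = 4
    w_shape: float = 1.0
    w_elec: float = 1.0
    w_desolv: float = 1.0

    # search & output
    top_k: int = 2000
    seed: int = 0
    workers: int = 1  # angle-parallel workers (1 = serial)
    profile: bool = True
    heavy_only: bool = True
    include_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.margin < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if self.n_theta_cap is not None and self.n_theta_cap < 0:
            raise ValueError(f"n_theta_cap must be >= 0, got {self.n_theta_cap}")
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")

    @property
    def score_params(self) -> ScoreParams:
        return ScoreParams(
            surface_value=self.surface_value,
            core_value=self.core_value,
            surface_thickness=self.surface_thickness,
            elec_clamp=self.elec_clamp,
            desolv_cap=self.desolv_cap,
            w_shape=self.w_shape,
            w_elec=self.w_elec,
            w_desolv=self.w_desolv,
        )

    def rotation_set(self) -> RotationSet:
        """Resolve the rotation set: external file if given, else the Euler grid."""
        if self.rotation_file is not None:
            rs = import_rotations(self.rotation_file)
            cap = self.n_theta_cap
            if cap is not None and rs.n_theta > cap:
                rs = RotationSet(
                    step_theta=rs.step_theta,
                    eulers=rs.eulers[:cap],
                    matrices=rs.matrices[:cap],
                    truncated_from=rs.n_theta,
                )
            return rs
        return default_rotation_set(self.rotation_step, cap=self.n_theta_cap)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a YAML config file, with keyword overrides taking precedence."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)
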