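"""Run configuration: a strict (unknown keys rejected) YAML-backed schema
mirroring the stage defaults, logged in full for provenance."""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnsembleSection(_Strict):
    n_replicates: int = 512
    duration_us: float = 2.0
    timestep_us: float = 1e-3
    d_trans: float = 4.0
    d_rot: float = 8000.0
    box: tuple[float, float] = (17.0, 17.0)
    start_com_separation: float = 8.4
    frame_stride_us: float = 0.02
    temperature: float = 310.0


class OrientationSection(_Strict):
    times_us: list[float] = Field(default=[0.0, 0.5, 1.0, 1.5, 2.0])
    dimer_cutoff: float = 1.0
    grid_n: int = 72
    bandwidth_deg: float = 8.0
    min_enrichment: float = 2.0
    min_population: int = 3
    diag_tol: float = 15.0
    pair_tol: float = 20.0
    angular_radius: float = 30.0


class ContactsSection(_Strict):
    cutoff: float = 0.5
    n_frames: int = 5
    window_us: float = 0.1
    min_count: int = 5
    bundle_fraction_threshold: float = 0.5
    persistence: int = 2


class MembraneSection(_Strict):
    grid_cell: float = 0.4
    window: str = "second_half"
    shell_width: float = 0.5


class ConvergenceSection(_Strict):
    tail_fraction: float = 0.25


class RunConfig(_Strict):
    seed: int = 0
    out_prefix: str = "dimerscope_run"
    traj_dir: str | None = None
    template_path: str | None = None
    log_level: str = "INFO"
    ensemble: EnsembleSection = Field(default_factory=EnsembleSection)
    orientation: OrientationSection = Field(default_factory=OrientationSection)
    contacts: ContactsSection = Field(default_factory=ContactsSection)
    membrane: MembraneSection = Field(default_factory=MembraneSection)
    convergence: ConvergenceSection = Field(default_factory=ConvergenceSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def log_provenance(self) -> None:
        """Print every effective parameter into the run log."""
        for line in yaml.safe_dump(self.model_dump(), sort_keys=True).splitlines():
            logger.info("config: %s", line)
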