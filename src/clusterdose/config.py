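"""Run configuration: a versioned YAML/JSON schema for the pipeline.

All physical settings are explicit in the config — nothing scientifically
meaningful is defaulted silently.  See ``examples/`` for complete files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .cluster import ClusterSpec, NanoagentSpec
from .dose_field import TransportConfig
from .kernels import (
    RadialBinning,
    RDDKernel,
    SyntheticKernelParams,
    build_standard_binning,
    make_synthetic_kernel,
    read_kernel,
)

__all__ = ["AgentConfig", "RunConfig", "load_config"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AgentConfig:
    """One nanoagent together with its kernel source and activation rate."""

    agent: NanoagentSpec
    kernel_path: Path | None = None
    synthetic_kernel: SyntheticKernelParams | None = None
    cluster_rate_per_gray: float | None = None  # divided by realized agent count

    def build_kernel(self, binning: RadialBinning) -> RDDKernel:
        if self.kernel_path is not None:
            return read_kernel(self.kernel_path)
        if self.synthetic_kernel is not None:
            return make_synthetic_kernel(self.synthetic_kernel, binning, self.agent.agent_id)
        raise ValueError(f"agent {self.agent.agent_id}: no kernel source configured")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    agents: Sequence[AgentConfig]
    cluster_radius: float
    fill_factor: float
    dose: float
    transport: TransportConfig
    ensemble_size: int = 100
    n_surface_points: int = 1000
    shell_r_max: float | None = None
    nucleus_radius: float = 7000.0
    cell_radius: float = 15000.0
    cluster_distances: Sequence[float] = ()
    targets: Sequence[str] = ("nucleus", "cytoplasm")
    lq: Mapping[str, float] | None = None  # alpha, beta, sensitive_volume_nm3
    seed: int = 0
    output_dir: Path = Path("out")
    normalize: bool = False
    raw: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble size must be >= 1")
        if not self.agents:
            raise ValueError("at least one agent must be configured")
        for t in self.targets:
            if t not in ("nucleus", "cytoplasm", "cell"):
                raise ValueError(f"unknown target {t!r}")

    def cluster_spec(self, agent_cfg: AgentConfig, seed: int) -> ClusterSpec:
        return ClusterSpec(self.cluster_radius, self.fill_factor, agent_cfg.agent, seed)

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _agent_from_dict(d: Mapping[str, Any]) -> AgentConfig:
    spec = NanoagentSpec(
        agent_id=d["agent_id"],
        core_radius=float(d["core_radius_nm"]),
        coating_thickness=float(d.get("coating_thickness_nm", 0.0)),
        core_density=float(d.get("core_density_g_cm3", 19.32)),
        core_gold_mass_fraction=float(d.get("core_gold_mass_fraction", 1.0)),
        ionisation_rate_per_gray=float(d.get("rate_per_gray_per_agent", 0.0)),
    )
    synth = None
    if "synthetic_kernel" in d:
        s = d["synthetic_kernel"]
        synth = SyntheticKernelParams(
            amplitude=float(s["amplitude_gy_nm2"]),
            attenuation_length=float(s["attenuation_length_nm"]),
            support_radius=float(s["support_radius_nm"]),
            bump_centers=tuple(s.get("bump_centers_nm", ())),
            bump_widths=tuple(s.get("bump_widths_nm", ())),
            bump_heights=tuple(s.get("bump_heights", ())),
        )
    kernel_path = Path(d["kernel_file"]) if "kernel_file" in d else None
    return AgentConfig(
        agent=spec,
        kernel_path=kernel_path,
        synthetic_kernel=synth,
        cluster_rate_per_gray=(
            float(d["cluster_rate_per_gray"]) if "cluster_rate_per_gray" in d else None
        ),
    )


def config_from_dict(data: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    version = int(data.get("schema_version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {version}")
    agents_raw = data.get("agents")
    if agents_raw is None and "agent" in data:
        agents_raw = [data["agent"]]
    if not agents_raw:
        raise ValueError("config must define 'agent' or 'agents'")
    agents = [_agent_from_dict(a) for a in agents_raw]
    if base_dir is not None:
        agents = [
            AgentConfig(
                a.agent,
                (base_dir / a.kernel_path) if a.kernel_path and not a.kernel_path.is_absolute() else a.kernel_path,
                a.synthetic_kernel,
                a.cluster_rate_per_gray,
            )
            for a in agents
        ]
        for a in agents:
            if a.kernel_path is not None and not a.kernel_path.exists():
                raise FileNotFoundError(f"kernel file not found: {a.kernel_path}")

    cl = data["cluster"]
    tr = data.get("transport", {})
    cell = data.get("cell", {})
    lq = data.get("lq")
    return RunConfig(
        agents=agents,
        cluster_radius=float(cl["radius_nm"]),
        fill_factor=float(cl["fill_factor"]),
        dose=float(data.get("dose_gy", 1.0)),
        transport=TransportConfig(
            stopping_power_ratio=float(tr.get("stopping_power_ratio", 1.0)),
            background_dose=float(data.get("dose_gy", 1.0)),
        ),
        ensemble_size=int(data.get("ensemble_size", 100)),
        n_surface_points=int(data.get("n_surface_points", 1000)),
        shell_r_max=(float(data["shell_r_max_nm"]) if "shell_r_max_nm" in data else None),
        nucleus_radius=float(cell.get("nucleus_radius_nm", 7000.0)),
        cell_radius=float(cell.get("cell_radius_nm", 15000.0)),
        cluster_distances=tuple(cell.get("distances_nm", ())),
        targets=tuple(cell.get("targets", ("nucleus", "cytoplasm"))),
        lq=(dict(lq) if lq else None),
        seed=int(data.get("seed", 0)),
        output_dir=Path(data.get("output_dir", "out")),
        normalize=bool(data.get("normalize", False)),
        raw=dict(data),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return config_from_dict(data, base_dir=path.parent)
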