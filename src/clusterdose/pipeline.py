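"""Config-driven orchestration: ensembles, placement sweeps, dose slices.

Every pipeline entry point is a pure function of (config, root seed): the
root seed is expanded into per-realization sub-seeds with a deterministic
generator, so identical inputs reproduce byte-identical output tables.
Only descriptive statistics (mean and population standard deviation over
the ensemble) are reported.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .activation import (
    SINGLE_EVENT_THRESHOLD,
    sample_activations_binomial,
    sample_activations_poisson,
    sample_sparse_realization,
)
from .cell_model import CellGeometry, LQParams, compute_integrals, dose_enhancement_factor
from .cluster import Cluster, ClusterSpec, gold_atom_ratio, pack_cluster, target_agent_count
from .config import AgentConfig, RunConfig
from .dose_field import local_enhancement
from .kernels import build_standard_binning
from .shells import ShellTable, shell_profile

logger = logging.getLogger(__name__)

__all__ = ["run_ensemble", "run_placement_sweep", "export_dose_slice"]

# above this agent count the full centre list is never materialised and the
# sparse single-event path is mandatory
_SPARSE_AGENT_LIMIT = 200_000


def _write_table(df: pd.DataFrame, path: Path, metadata: Mapping[str, str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for key, val in metadata.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _metadata(config: RunConfig, extra: Mapping[str, str] | None = None) -> dict[str, str]:
    meta = {
        "clusterdose_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config_hash": config.config_hash(),
        "seed": str(config.seed),
    }
    if extra:
        meta.update(extra)
    return meta


def _per_agent_rate(config: RunConfig, agent_cfg: AgentConfig, n_agents: int) -> float:
    if agent_cfg.cluster_rate_per_gray is not None:
        return agent_cfg.cluster_rate_per_gray / n_agents
    return agent_cfg.agent.ionisation_rate_per_gray


def _shell_r_max(config: RunConfig, kernel_support: float) -> float:
    r_max = config.shell_r_max
    if r_max is None:
        r_max = config.cluster_radius + kernel_support
    if config.cluster_distances:
        r_max = max(r_max, max(config.cluster_distances) + config.cell_radius)
    return r_max


def _one_realization(
    config: RunConfig,
    agent_cfg: AgentConfig,
    kernel,
    binning,
    seed: int,
) -> tuple[Cluster, ShellTable]:
    """Pack (or sparse-sample) one cluster, activate it, tabulate shells."""
    spec = config.cluster_spec(agent_cfg, seed)
    n_agents = target_agent_count(spec)
    rate = _per_agent_rate(config, agent_cfg, n_agents)
    mu = rate * config.dose
    rng = np.random.default_rng(seed)
    if n_agents > _SPARSE_AGENT_LIMIT:
        if mu > SINGLE_EVENT_THRESHOLD:
            raise ValueError(
                f"{n_agents} agents with per-agent mean {mu:.3g}: too large to pack "
                "and too active for the single-event path"
            )
        cluster, act = sample_sparse_realization(
            n_agents, rate, config.dose, config.cluster_radius,
            spec.agent.agent_radius, rng,
        )
    else:
        cluster = pack_cluster(spec)
        if mu <= SINGLE_EVENT_THRESHOLD:
            act = sample_activations_binomial(cluster, rate, config.dose, rng)
        else:
            act = sample_activations_poisson(cluster, rate, config.dose, rng)
    table = shell_profile(
        act, cluster, kernel, binning, config.transport,
        n_points=config.n_surface_points,
        r_max=_shell_r_max(config, kernel.support_radius),
    )
    return cluster, table


def _sub_seeds(root_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(root_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_ensemble(config: RunConfig, out_dir: Path | None = None) -> dict[str, pd.DataFrame]:
    """Ensemble statistics of shell profiles and target integrals.

    For each configured agent, ``ensemble_size`` independent clusters are
    packed and activated; the per-radius mean and standard deviation of
    <L>, S1*dr and S2*dr are tabulated, along with per-placement I1/I2
    statistics (and DEF when LQ parameters are configured).  Writes
    ``shells_<agent>.csv`` and ``integrals_<agent>.csv`` plus a manifest.
    """
    t0 = time.perf_counter()
    out_dir = Path(out_dir) if out_dir is not None else config.output_dir
    binning = build_standard_binning()
    if config.transport.stopping_power_ratio == 1.0:
        logger.warning("stopping-power ratio k = 1: mixture path-length correction disabled")
    results: dict[str, pd.DataFrame] = {}
    stage_times: dict[str, float] = {}
    for agent_cfg in config.agents:
        agent_id = agent_cfg.agent.agent_id
        t_agent = time.perf_counter()
        kernel = agent_cfg.build_kernel(binning)
        if config.cluster_distances:
            needed = max(config.cluster_distances) + config.cell_radius
            reach = config.cluster_radius + kernel.support_radius
            if reach < needed:
                logger.warning(
                    "agent %s: kernel support ends at %g nm from the cluster centre "
                    "but targets extend to %g nm; the field is taken as zero beyond "
                    "the support", agent_id, reach, needed,
                )
        seeds = _sub_seeds(config.seed, config.ensemble_size)
        mean_L_rows, s1dr_rows, s2dr_rows = [], [], []
        integ_rows = []
        radii = widths = None
        for seed in seeds:
            _, table = _one_realization(config, agent_cfg, kernel, binning, seed)
            radii, widths = table.radii, table.bin_widths
            mean_L_rows.append(table.mean_L)
            s1dr_rows.append(table.S1 * widths)
            s2dr_rows.append(table.S2 * widths)
            for d in config.cluster_distances:
                geom = CellGeometry(
                    config.nucleus_radius, config.cell_radius, d, config.cluster_radius
                )
                for target in config.targets:
                    integ = compute_integrals(table, geom, target)
                    integ_rows.append(
                        {"seed": seed, "d_nm": d, "target": target,
                         "I1_nm3": integ.I1, "I2_nm3": integ.I2}
                    )
        mean_L = np.array(mean_L_rows)
        s1dr = np.array(s1dr_rows)
        s2dr = np.array(s2dr_rows)
        shells_df = pd.DataFrame(
            {
                "radius_nm": radii,
                "dr_nm": widths,
                "mean_L_mean": mean_L.mean(axis=0),
                "mean_L_std": mean_L.std(axis=0),
                "S1dr_nm3_mean": s1dr.mean(axis=0),
                "S1dr_nm3_std": s1dr.std(axis=0),
                "S2dr_nm3_mean": s2dr.mean(axis=0),
                "S2dr_nm3_std": s2dr.std(axis=0),
            }
        )
        results[f"shells_{agent_id}"] = shells_df
        meta = _metadata(config, {"agent_id": agent_id, "ensemble_size": str(config.ensemble_size)})
        _write_table(shells_df, out_dir / f"shells_{agent_id}.csv", meta)

        if integ_rows:
            per_cluster = pd.DataFrame(integ_rows)
            grouped = (
                per_cluster.groupby(["d_nm", "target"], sort=True)
                .agg(
                    I1_nm3_mean=("I1_nm3", "mean"),
                    I1_nm3_std=("I1_nm3", lambda x: float(np.std(x))),
                    I2_nm3_mean=("I2_nm3", "mean"),
                    I2_nm3_std=("I2_nm3", lambda x: float(np.std(x))),
                )
                .reset_index()
            )
            if config.lq is not None:
                lq = LQParams(
                    alpha=float(config.lq["alpha_per_gy"]),
                    beta=float(config.lq["beta_per_gy2"]),
                    dose=config.dose,
                    sensitive_volume=float(config.lq["sensitive_volume_nm3"]),
                )
                grouped["DEF_mean"] = [
                    dose_enhancement_factor(lq, i1) for i1 in grouped["I1_nm3_mean"]
                ]
            results[f"integrals_{agent_id}"] = grouped
            _write_table(grouped, out_dir / f"integrals_{agent_id}.csv", meta)
        stage_times[agent_id] = time.perf_counter() - t_agent

    _write_manifest(config, out_dir, stage_times, time.perf_counter() - t0)
    return results


def run_placement_sweep(config: RunConfig, out_dir: Path | None = None) -> pd.DataFrame:
    """I1/I2 per (agent, placement distance, target), averaged over an ensemble.

    Adds a gold-atom-ratio column relative to the first configured agent
    and, when ``normalize`` is set, I1/I2 columns normalised to the first
    agent at the smallest distance with the cytoplasm target (or the
    first configured target if cytoplasm is absent).
    """
    if not config.cluster_distances:
        raise ValueError("placement sweep requires cell.distances_nm")
    out_dir = Path(out_dir) if out_dir is not None else config.output_dir
    ens = run_ensemble(config, out_dir=out_dir)
    ref_agent = config.agents[0].agent
    rows = []
    for agent_cfg in config.agents:
        key = f"integrals_{agent_cfg.agent.agent_id}"
        if key not in ens:
            continue
        df = ens[key].copy()
        df.insert(0, "agent_id", agent_cfg.agent.agent_id)
        df["gold_atom_ratio_vs_first_agent"] = gold_atom_ratio(agent_cfg.agent, ref_agent)
        rows.append(df)
    sweep = pd.concat(rows, ignore_index=True)
    if config.normalize:
        ref_target = "cytoplasm" if "cytoplasm" in config.targets else config.targets[0]
        ref = sweep[
            (sweep["agent_id"] == ref_agent.agent_id)
            & (sweep["d_nm"] == min(config.cluster_distances))
            & (sweep["target"] == ref_target)
        ]
        ref_i1 = float(ref["I1_nm3_mean"].iloc[0])
        if ref_i1 > 0:
            sweep["I1_norm"] = sweep["I1_nm3_mean"] / ref_i1
            sweep["I2_norm"] = sweep["I2_nm3_mean"] / ref_i1
    _write_table(sweep, out_dir / "placement_sweep.csv", _metadata(config))
    return sweep


def export_dose_slice(
    config: RunConfig,
    axis: str = "z",
    offset: float = 0.0,
    pitch: float = 50.0,
    half_extent: float | None = None,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Local-enhancement map on a planar grid through one cluster realization.

    The plane is normal to ``axis`` at ``offset`` (nm); grid points are
    spaced ``pitch`` nm out to ``half_extent`` each side of the cluster
    centre.  Interior and exterior points are both evaluated.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError("axis must be one of x, y, z")
    out_dir = Path(out_dir) if out_dir is not None else config.output_dir
    agent_cfg = config.agents[0]
    binning = build_standard_binning()
    kernel = agent_cfg.build_kernel(binning)
    seed = _sub_seeds(config.seed, 1)[0]

    spec = config.cluster_spec(agent_cfg, seed)
    n_agents = target_agent_count(spec)
    rate = _per_agent_rate(config, agent_cfg, n_agents)
    rng = np.random.default_rng(seed)
    if n_agents > _SPARSE_AGENT_LIMIT:
        cluster, act = sample_sparse_realization(
            n_agents, rate, config.dose, config.cluster_radius,
            spec.agent.agent_radius, rng,
        )
    else:
        cluster = pack_cluster(spec)
        mu = rate * config.dose
        if mu <= SINGLE_EVENT_THRESHOLD:
            act = sample_activations_binomial(cluster, rate, config.dose, rng)
        else:
            act = sample_activations_poisson(cluster, rate, config.dose, rng)

    if half_extent is None:
        half_extent = 2.0 * config.cluster_radius
    coords = np.arange(-half_extent, half_extent + 0.5 * pitch, pitch)
    u, v = np.meshgrid(coords, coords, indexing="ij")
    flat_u, flat_v = u.ravel(), v.ravel()
    k = "xyz".index(axis)
    pts = np.zeros((flat_u.size, 3))
    in_plane = [m for m in range(3) if m != k]
    pts[:, in_plane[0]] = flat_u
    pts[:, in_plane[1]] = flat_v
    pts[:, k] = offset
    L = local_enhancement(act, cluster, kernel, pts, config.transport)
    df = pd.DataFrame(
        {"x_nm": pts[:, 0], "y_nm": pts[:, 1], "z_nm": pts[:, 2], "L": L}
    )
    _write_table(
        df, out_dir / f"slice_{axis}_{offset:g}.csv",
        _metadata(config, {"axis": axis, "offset_nm": str(offset), "pitch_nm": str(pitch)}),
    )
    return df


def _write_manifest(
    config: RunConfig, out_dir: Path, stage_times: Mapping[str, float], total: float
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "clusterdose_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "stage_wall_times_s": dict(stage_times),
        "total_wall_time_s": total,
    }
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
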