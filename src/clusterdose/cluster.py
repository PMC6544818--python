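"""Stochastic packing of nanoagents into spherical clusters.

Nanoagents (coated gold nanoparticles, or small gold-bearing molecules
treated as nano-objects) are packed into a spherical cluster by random
sequential addition: centres are drawn uniformly in the ball that keeps
the whole agent inside the cluster and rejected on overlap with any
previously placed agent.  This realises a uniform placement density at
the dilute fill factors of interest (~10%), far below jamming.

Gold-atom accounting utilities quantify how many heavy atoms a packing
delivers, the quantity that ultimately controls the physical dose
enhancement of a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "NanoagentSpec",
    "ClusterSpec",
    "Cluster",
    "PackingError",
    "target_agent_count",
    "pack_cluster",
    "gold_atoms_per_agent",
    "gold_atom_ratio",
    "mean_gold_fraction_profile",
    "write_cluster",
    "read_cluster",
    "GOLD_MOLAR_MASS",
    "AVOGADRO",
    "GOLD_DENSITY",
]

GOLD_MOLAR_MASS = 196.97  # g/mol
AVOGADRO = 6.02214076e23  # 1/mol
GOLD_DENSITY = 19.32  # g/cm^3, bulk gold


@dataclass(frozen=True)
class NanoagentSpec:
    """Geometry, composition and per-agent ionisation rate of one nanoagent.

    ``core_radius`` and ``coating_thickness`` are nm; ``core_density`` is
    g/cm^3; ``core_gold_mass_fraction`` is the mass fraction of gold in
    the core (1 for a pure gold nanoparticle core, < 1 for a gold-bearing
    molecule); ``ionisation_rate_per_gray`` is the expected number of
    ionisation events per agent per Gy of applied dose.
    """

    agent_id: str
    core_radius: float
    coating_thickness: float = 0.0
    core_density: float = GOLD_DENSITY
    core_gold_mass_fraction: float = 1.0
    ionisation_rate_per_gray: float = 0.0

    def __post_init__(self) -> None:
        if self.core_radius <= 0:
            raise ValueError("core radius must be > 0")
        if self.coating_thickness < 0:
            raise ValueError("coating thickness must be >= 0")
        if self.core_density <= 0:
            raise ValueError("core density must be > 0")
        if not 0.0 <= self.core_gold_mass_fraction <= 1.0:
            raise ValueError("gold mass fraction must lie in [0, 1]")
        if self.ionisation_rate_per_gray < 0:
            raise ValueError("ionisation rate must be >= 0")

    @property
    def agent_radius(self) -> float:
        return self.core_radius + self.coating_thickness


# Reference agents.  Ionisation rates correspond to cluster-level rates of
# ~10, ~1 and ~0.1 events/Gy for 500 nm clusters at 10% fill of the 25 nm,
# 1 nm and auranofin agents respectively.
GOLD_25NM = NanoagentSpec(
    "aunp-25nm", core_radius=25.0, coating_thickness=1.0,
    ionisation_rate_per_gray=10.0 / 711,
)
GOLD_1NM = NanoagentSpec(
    "aunp-1nm", core_radius=1.0, coating_thickness=1.0,
    ionisation_rate_per_gray=1.0 / 1_562_500,
)
# Auranofin modelled as a 1 nm-radius nano-object of density 1.7 g/cm3.
# The effective gold mass fraction of the nano-object is a user input; the
# molecular mass fraction (Au ~0.29 of C20H34AuO9PS) is a starting point only.
AURANOFIN = NanoagentSpec(
    "auranofin", core_radius=1.0, coating_thickness=0.0, core_density=1.7,
    core_gold_mass_fraction=0.29, ionisation_rate_per_gray=0.1 / 12_500_000,
)


@dataclass(frozen=True)
class ClusterSpec:
    """Cluster radius (nm), volumetric fill factor and the agent packed."""

    cluster_radius: float
    fill_factor: float
    agent: NanoagentSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_radius <= self.agent.agent_radius:
            raise ValueError("cluster radius must exceed the agent radius")
        if not 0.0 < self.fill_factor <= 0.3:
            raise ValueError(
                "fill factor must lie in (0, 0.3]; dense packings are unsupported"
            )


@dataclass
class Cluster:
    """A packed cluster: agent centres (nm, cluster-centred frame)."""

    centers: np.ndarray
    agent_radius: float
    cluster_radius: float
    spec: ClusterSpec | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.centers = centers
        self.metadata = dict(self.metadata)

    @property
    def n_agents(self) -> int:
        return self.centers.shape[0]

    def check_invariants(self) -> None:
        """Raise if any agents overlap or poke out of the cluster."""
        norms = np.linalg.norm(self.centers, axis=1)
        if np.any(norms > self.cluster_radius - self.agent_radius + 1e-9):
            raise ValueError("agent not contained in the cluster")
        if self.n_agents > 1:
            tree = cKDTree(self.centers)
            pairs = tree.query_pairs(2 * self.agent_radius - 1e-9)
            if pairs:
                raise ValueError(f"{len(pairs)} overlapping agent pairs")


class PackingError(RuntimeError):
    """Raised when random sequential addition exhausts its attempt budget."""

    def __init__(self, target: int, achieved: int):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"packing failed: placed {achieved} of {target} agents "
            "within the attempt budget"
        )


def target_agent_count(spec: ClusterSpec) -> int:
    """Number of agents realising the fill factor.

    ``round(fill * R_cluster^3 / r_agent^3)`` — whole-agent (core+coating)
    volume counts toward the fill.
    """
    count = int(round(spec.fill_factor * spec.cluster_radius**3 / spec.agent.agent_radius**3))
    if count < 1:
        raise ValueError("fill factor unrealizable: fewer than one agent fits the target")
    return count


class _CellGrid:
    """Uniform spatial hash for overlap queries; cell size = agent diameter.

    Output is identical to the naive all-pairs check: any centre within
    2*r_agent of a candidate lies in one of the 27 neighbouring cells.
    """

    def __init__(self, cell_size: float):
        self.cell = cell_size
        self.grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.floor(p / self.cell).astype(int))

    def conflicts(self, p: np.ndarray, min_dist: float) -> bool:
        kx, ky, kz = self._key(p)
        md2 = min_dist * min_dist
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.grid.get((kx + dx, ky + dy, kz + dz), ()):
                        d = p - q
                        if d @ d < md2:
                            return True
        return False

    def insert(self, p: np.ndarray) -> None:
        self.grid.setdefault(self._key(p), []).append(p)


def pack_cluster(
    spec: ClusterSpec,
    rng: np.random.Generator | None = None,
    attempt_budget_per_agent: int = 1000,
) -> Cluster:
    """Pack ``target_agent_count(spec)`` agents by random sequential addition.

    Candidate centres are drawn uniformly in the ball of radius
    ``cluster_radius - agent_radius`` (so the whole agent stays inside)
    and rejected if any previously placed centre lies within one agent
    diameter.  Deterministic for a fixed ``spec.seed`` when no generator
    is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_target = target_agent_count(spec)
    r_agent = spec.agent.agent_radius
    r_allowed = spec.cluster_radius - r_agent
    grid = _CellGrid(2 * r_agent)
    centers: list[np.ndarray] = []
    budget = attempt_budget_per_agent * n_target
    attempts = 0
    while len(centers) < n_target:
        if attempts >= budget:
            raise PackingError(n_target, len(centers))
        # uniform in the allowed ball, by direction x radius^(1/3)
        batch = min(4 * (n_target - len(centers)) + 16, 65536)
        attempts += batch
        vec = rng.normal(size=(batch, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        radii = r_allowed * rng.random(batch) ** (1.0 / 3.0)
        cands = vec * radii[:, None]
        for p in cands:
            if len(centers) == n_target:
                break
            if not grid.conflicts(p, 2 * r_agent):
                grid.insert(p)
                centers.append(p)
    return Cluster(
        np.array(centers), r_agent, spec.cluster_radius, spec,
        {"seed": str(spec.seed)},
    )


def gold_atoms_per_agent(agent: NanoagentSpec) -> float:
    """Number of gold atoms in one agent's core.

    ``rho_core * (4/3) pi r_core^3 * w_Au * N_A / M_Au`` with the core
    density converted from g/cm^3 to g/nm^3 (1 cm^3 = 1e21 nm^3).
    """
    core_volume_nm3 = (4.0 / 3.0) * np.pi * agent.core_radius**3
    core_mass_g = agent.core_density * 1e-21 * core_volume_nm3
    return core_mass_g * agent.core_gold_mass_fraction * AVOGADRO / GOLD_MOLAR_MASS


def gold_atom_ratio(a: NanoagentSpec, b: NanoagentSpec) -> float:
    """Gold atoms packed per unit cluster volume, agent ``a`` relative to ``b``.

    At equal fill factor the number of agents scales as 1/agent volume, so
    the ratio is (atoms_a / V_agent_a) / (atoms_b / V_agent_b).  For pure
    gold cores of equal density this reduces to
    ``(r_core_a/r_agent_a)^3 / (r_core_b/r_agent_b)^3``.
    """
    per_volume_a = gold_atoms_per_agent(a) / a.agent_radius**3
    per_volume_b = gold_atoms_per_agent(b) / b.agent_radius**3
    if per_volume_b == 0:
        raise ZeroDivisionError("agent b carries no gold")
    return per_volume_a / per_volume_b


def mean_gold_fraction_profile(
    spec: ClusterSpec,
    n_clusters: int = 100,
    seed: int = 0,
    n_radial_bins: int = 20,
    n_sample_points: int = 20000,
):
    """Ensemble-average gold volume fraction vs distance from the cluster centre.

    Monte-Carlo over ``n_clusters`` independent packings: points are drawn
    uniformly in the cluster ball, tested against agent cores with a KD
    tree, and binned radially.  The profile is flat at
    ``fill * (r_core/r_agent)^3`` deep inside the cluster and dips near
    the surface because no agent centre can lie closer than one agent
    radius to the cluster edge.

    Returns a ``pandas.DataFrame`` with columns ``radius_nm`` (bin centre)
    and ``gold_fraction``.
    """
    import pandas as pd

    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, spec.cluster_radius, n_radial_bins + 1)
    hits = np.zeros(n_radial_bins)
    totals = np.zeros(n_radial_bins)
    r_core = spec.agent.core_radius
    for _ in range(n_clusters):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cluster = pack_cluster(
            ClusterSpec(spec.cluster_radius, spec.fill_factor, spec.agent, sub_seed)
        )
        tree = cKDTree(cluster.centers)
        vec = rng.normal(size=(n_sample_points, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        radii = spec.cluster_radius * rng.random(n_sample_points) ** (1.0 / 3.0)
        pts = vec * radii[:, None]
        dist, _ = tree.query(pts, k=1)
        in_core = dist <= r_core
        idx = np.clip(np.searchsorted(edges, radii, side="right") - 1, 0, n_radial_bins - 1)
        np.add.at(totals, idx, 1.0)
        np.add.at(hits, idx, in_core.astype(float))
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, hits / totals, 0.0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"radius_nm": centres, "gold_fraction": frac})


def write_cluster(cluster: Cluster, path: str | Path) -> None:
    """Write agent centres as CSV with ``#`` metadata lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# agent_radius_nm={float(cluster.agent_radius)!r}\n")
        fh.write(f"# cluster_radius_nm={float(cluster.cluster_radius)!r}\n")
        for key, val in cluster.metadata.items():
            fh.write(f"# {key}={val}\n")
        fh.write("x_nm,y_nm,z_nm\n")
        for x, y, z in cluster.centers:
            fh.write(f"{float(x)!r},{float(y)!r},{float(z)!r}\n")


def read_cluster(path: str | Path) -> Cluster:
    """Read a cluster written by :func:`write_cluster`."""
    path = Path(path)
    metadata: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    metadata[key.strip()] = val.strip()
                continue
            if line.startswith("x_nm"):
                continue
            rows.append([float(f) for f in line.split(",")])
    agent_radius = float(metadata.pop("agent_radius_nm"))
    cluster_radius = float(metadata.pop("cluster_radius_nm"))
    return Cluster(np.array(rows), agent_radius, cluster_radius, None, metadata)
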