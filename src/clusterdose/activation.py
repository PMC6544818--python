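"""Sampling of ionisation (activation) events in packed nanoagents.

Irradiating a cluster to a dose ``D`` ionises each agent a random number
of times.  Two mathematically equivalent sampling paths are provided:

* a Poisson path, drawing each agent's event count independently from
  Poisson(rate * D) — needed when multiple events per agent are not
  negligible (large nanoparticles);
* a binomial path for the single-event regime, drawing only the number of
  activated agents from Binomial(N, 1 - exp(-rate * D)) and assigning one
  event each — this never materialises per-agent state and scales to
  clusters of millions of small agents.

Agents with zero events are pruned; only activated agents enter the dose
superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cluster import Cluster

__all__ = [
    "ActivationSet",
    "sample_activations_poisson",
    "sample_activations_binomial",
    "sample_sparse_realization",
    "prob_any_double_event",
    "write_activations",
    "read_activations",
    "SINGLE_EVENT_THRESHOLD",
]

# Per-agent mean below which double events are negligible (< 5e-7 per agent)
# and the binomial single-event path is statistically indistinguishable from
# the Poisson path.
SINGLE_EVENT_THRESHOLD = 1e-3


@dataclass
class ActivationSet:
    """Sparse activation record for one irradiation realization.

    ``indices`` are the activated agents (unique, valid for the cluster
    the set was sampled from) and ``counts`` their ionisation event
    numbers, all >= 1.
    """

    indices: np.ndarray
    counts: np.ndarray
    dose: float
    per_agent_rate: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.indices.shape != self.counts.shape:
            raise ValueError("indices and counts must align")
        if np.any(self.counts < 1):
            raise ValueError("all stored event counts must be >= 1")
        if self.indices.size and np.unique(self.indices).size != self.indices.size:
            raise ValueError("agent indices must be unique")

    @property
    def n_activated(self) -> int:
        return self.indices.size

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())


def _check_rate_dose(per_agent_rate: float, dose: float) -> None:
    if per_agent_rate < 0:
        raise ValueError("ionisation rate must be >= 0")
    if dose < 0:
        raise ValueError("dose must be >= 0")


def sample_activations_poisson(
    cluster: Cluster | int,
    per_agent_rate: float,
    dose: float,
    rng: np.random.Generator,
) -> ActivationSet:
    """Draw each agent's event count from Poisson(rate * dose), pruning zeros.

    ``cluster`` may be a packed :class:`Cluster` or a bare agent count.
    """
    _check_rate_dose(per_agent_rate, dose)
    n = cluster if isinstance(cluster, int) else cluster.n_agents
    mu = per_agent_rate * dose
    counts = rng.poisson(mu, size=n)
    active = np.nonzero(counts)[0]
    return ActivationSet(active, counts[active], dose, per_agent_rate)


def sample_activations_binomial(
    cluster: Cluster | int,
    per_agent_rate: float,
    dose: float,
    rng: np.random.Generator,
    single_event_threshold: float = SINGLE_EVENT_THRESHOLD,
) -> ActivationSet:
    """Single-event path: draw the activated-agent count, assign one event each.

    The number of activated agents follows Binomial(N, 1 - exp(-mu)) with
    ``mu = rate * dose``; which agents they are is a uniform draw without
    replacement.  Refuses per-agent means above ``single_event_threshold``
    where double events are no longer negligible — use the Poisson path.
    """
    _check_rate_dose(per_agent_rate, dose)
    mu = per_agent_rate * dose
    if mu > single_event_threshold:
        raise ValueError(
            f"per-agent mean {mu:.3g} exceeds the single-event threshold "
            f"{single_event_threshold:g}; use sample_activations_poisson"
        )
    n = cluster if isinstance(cluster, int) else cluster.n_agents
    p_active = -np.expm1(-mu)
    m = int(rng.binomial(n, p_active))
    indices = rng.choice(n, size=m, replace=False) if m else np.empty(0, dtype=np.int64)
    indices = np.sort(indices)
    return ActivationSet(indices, np.ones(m, dtype=np.int64), dose, per_agent_rate)


def sample_sparse_realization(
    n_agents: int,
    per_agent_rate: float,
    dose: float,
    cluster_radius: float,
    agent_radius: float,
    rng: np.random.Generator,
) -> tuple[Cluster, ActivationSet]:
    """Binomial path without a packed cluster, for very large agent counts.

    Only the activated agents are given coordinates, drawn uniformly in
    the ball of radius ``cluster_radius - agent_radius``; at single-event
    fill levels the overlap probability among the handful of activated
    agents is negligible.  Returns a sparse cluster holding just those
    agents and the matching activation set (indices 0..m-1).
    """
    act = sample_activations_binomial(n_agents, per_agent_rate, dose, rng)
    m = act.n_activated
    r_allowed = cluster_radius - agent_radius
    vec = rng.normal(size=(m, 3))
    if m:
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    radii = r_allowed * rng.random(m) ** (1.0 / 3.0)
    centers = vec * radii[:, None]
    sparse = Cluster(centers, agent_radius, cluster_radius, None,
                     {"sparse": "true", "n_agents_nominal": str(n_agents)})
    act_local = ActivationSet(np.arange(m), act.counts, dose, per_agent_rate)
    return sparse, act_local


def prob_any_double_event(n_agents: int, cluster_mean_events: float) -> float:
    """Probability that at least one agent undergoes >= 2 ionisation events.

    With per-agent mean ``mu = cluster_mean_events / n_agents`` and
    independent Poisson counts, ``1 - (exp(-mu) (1 + mu))^N``, evaluated
    in log space for numerical stability at large N.
    """
    if n_agents < 1:
        raise ValueError("need at least one agent")
    if cluster_mean_events < 0:
        raise ValueError("mean event count must be >= 0")
    if cluster_mean_events == 0:
        return 0.0
    mu = cluster_mean_events / n_agents
    log_p_le1 = np.log1p(mu) - mu  # log of P(count <= 1) per agent
    return float(-np.expm1(n_agents * log_p_le1))


def write_activations(act: ActivationSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# dose_gy={float(act.dose)!r}\n")
        fh.write(f"# per_agent_rate={float(act.per_agent_rate)!r}\n")
        fh.write("agent_index,n_events\n")
        for i, n in zip(act.indices, act.counts):
            fh.write(f"{i},{n}\n")


def read_activations(path: str | Path) -> ActivationSet:
    path = Path(path)
    metadata: dict[str, str] = {}
    idx: list[int] = []
    cnt: list[int] = []
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
            if line.startswith("agent_index"):
                continue
            a, _, b = line.partition(",")
            idx.append(int(a))
            cnt.append(int(b))
    return ActivationSet(
        np.array(idx, dtype=np.int64),
        np.array(cnt, dtype=np.int64),
        float(metadata.get("dose_gy", "nan")),
        float(metadata.get("per_agent_rate", "nan")),
    )
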