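"""Local energy enhancement by kernel superposition.

The extra dose at a field point is the sum over activated agents of the
agent's radial dose kernel evaluated at an *effective* distance

    g(r) = r_np + k * l_in + l_out,

where ``r_np`` is the agent radius, ``l_in`` the path through the cluster
outside the source agent, ``l_out`` the remaining path in water, and
``k`` the asymptotic ratio of electron stopping power in the gold/water
mixture to that in pure water.  Stretching the in-cluster path by ``k``
accounts, in a mean-field sense, for the extra energy lost traversing
the mixture; scattering by other agents is neglected (the geometry is
quasi-spherically symmetric).  The local enhancement is

    L(r_j) = sum_i n_i RDD(g(|r_i - r_j|)) / D,

the ratio of nanoagent-deposited energy to the uniform background dose
``D`` at the same point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .activation import ActivationSet
from .cluster import Cluster
from .kernels import RDDKernel

__all__ = [
    "TransportConfig",
    "segment_cluster_chord",
    "effective_distance",
    "effective_distance_line_integral",
    "local_enhancement",
]


@dataclass(frozen=True)
class TransportConfig:
    """Mixture stopping-power ratio ``k`` and applied background dose (Gy).

    ``k = 1`` disables the mixture path-length correction (pure water).
    There is no physical default for k: it depends on the gold loading of
    the cluster and must be supplied by the user.
    """

    stopping_power_ratio: float = 1.0
    background_dose: float = 1.0

    def __post_init__(self) -> None:
        if self.stopping_power_ratio <= 0:
            raise ValueError("stopping power ratio must be > 0")
        if self.background_dose <= 0:
            raise ValueError("background dose must be > 0")


def segment_cluster_chord(p_source, p_field, cluster_radius: float) -> np.ndarray | float:
    """Length of segment [p_source, p_field] inside the cluster ball.

    The cluster ball is centred at the origin.  Accepts single points
    (shape (3,)) or broadcastable stacks (..., 3); the source point(s) are
    assumed inside the ball so the intersection interval starts at 0.
    """
    a = np.asarray(p_source, dtype=float)
    b = np.asarray(p_field, dtype=float)
    scalar = a.ndim == 1 and b.ndim == 1
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    a, b = np.broadcast_arrays(a, b)
    d = b - a
    seg_len = np.linalg.norm(d, axis=-1)
    # solve |a + t d|^2 = R^2 for t along the unit interval
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(seg_len[..., None] > 0, d / seg_len[..., None], 0.0)
    au = np.einsum("...i,...i->...", a, u)
    aa = np.einsum("...i,...i->...", a, a)
    disc = au**2 - (aa - cluster_radius**2)
    # source inside ball => disc >= 0; exit parameter along the ray
    t_exit = -au + np.sqrt(np.maximum(disc, 0.0))
    chord = np.minimum(seg_len, np.maximum(t_exit, 0.0))
    return float(chord[0]) if scalar else chord


def effective_distance(
    p_source,
    p_field,
    cluster_radius: float,
    r_np: float,
    k: float,
) -> np.ndarray | float:
    """Effective source-to-field distance ``g = r_np + k*l_in + l_out``.

    ``l_in = chord - r_np`` (clamped at 0) is the in-cluster path outside
    the source agent and ``l_out`` the remaining path to the field point.
    The source agent's own radius is never scaled by ``k``: the kernel
    already includes intra-agent attenuation.  For ``k == 1`` the
    Euclidean distance is returned directly, so the correction vanishes
    identically.  Field points inside the source agent (distance < r_np)
    are returned at their Euclidean distance with no correction; the
    derivation of ``g`` assumes the electron exits the agent.
    """
    a = np.asarray(p_source, dtype=float)
    b = np.asarray(p_field, dtype=float)
    scalar = a.ndim == 1 and b.ndim == 1
    dist = np.linalg.norm(b - a, axis=-1)
    if k == 1.0:
        return float(dist) if scalar else dist
    chord = np.asarray(segment_cluster_chord(p_source, p_field, cluster_radius))
    if scalar:
        chord = chord.reshape(())
    l_in = np.maximum(chord - r_np, 0.0)
    l_out = dist - chord
    g = r_np + k * l_in + l_out
    g = np.where(dist < r_np, dist, g)
    return float(g) if scalar else g


def effective_distance_line_integral(
    p_source,
    p_field,
    stopping_ratio_profile: Callable[[np.ndarray], float],
    r_np: float,
) -> float:
    """Reference path-length correction by direct line integration.

    ``g = r_np + int_{r_np}^{|b-a|} ratio(a + s*u) ds`` along the segment,
    with the profile giving the local stopping-power ratio at each point.
    Reduces to :func:`effective_distance` for a profile that is constant
    ``k`` inside the cluster ball and 1 outside.  Scalar points only; this
    is an oracle for testing, not the production path.
    """
    a = np.asarray(p_source, dtype=float)
    b = np.asarray(p_field, dtype=float)
    dist = float(np.linalg.norm(b - a))
    if dist <= r_np:
        return dist
    u = (b - a) / dist

    def integrand(s: float) -> float:
        return float(stopping_ratio_profile(a + s * u))

    val, _ = quad(integrand, r_np, dist, limit=200, epsabs=1e-12, epsrel=1e-12)
    return r_np + val


def local_enhancement(
    activations: ActivationSet,
    cluster: Cluster,
    kernel: RDDKernel,
    p_field,
    cfg: TransportConfig,
) -> np.ndarray | float:
    """Local energy enhancement L at one or many field points.

    ``p_field`` may be a single point (3,) or a stack (M, 3); returns a
    scalar or an array of M values.  Vectorised over sources and field
    points; identical to the scalar double loop.
    """
    pts = np.asarray(p_field, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)

    if activations.n_activated == 0:
        out = np.zeros(pts.shape[0])
        return float(out[0]) if scalar else out
    if np.any(activations.indices >= cluster.n_agents) or np.any(activations.indices < 0):
        raise IndexError("activation indices out of range for this cluster")

    sources = cluster.centers[activations.indices]  # (S, 3)
    counts = activations.counts.astype(float)  # (S,)
    # pairwise effective distances, shape (M, S)
    g = effective_distance(
        sources[None, :, :],
        pts[:, None, :],
        cluster.cluster_radius,
        cluster.agent_radius,
        cfg.stopping_power_ratio,
    )
    dose = kernel.evaluate(np.ravel(g)).reshape(g.shape)
    L = dose @ counts / cfg.background_dose
    return float(L[0]) if scalar else L
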