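"""Cell-scale geometry and local-effect-model enhancement metrics.

A spherical cell (radius ``r_cell``) with a concentric spherical nucleus
(radius ``r_nucleus``) hosts a nanoagent cluster whose centre sits at
distance ``d`` from the cell centre.  Because the ensemble of clusters
has no preferred orientation, the volume integrals of the enhancement
field over a sensitive target reduce to radial quadratures

    I1 = int S1(r) * Omega(r)/(4 pi) dr,
    I2 = int S2(r) * Omega(r)/(4 pi) dr,

where Omega(r) is the solid angle of the sphere of radius ``r`` centred
on the cluster that lies inside the target (nucleus, cytoplasm or whole
cell).  I1 is the total extra dose (nm^3 at 1 Gy background) delivered
to the target by one cluster; within the local effect model it drives
the expected lethal-lesion count and the dose enhancement factor

    DEF = I1 (alpha + 2 beta D) / (V_sens (alpha + beta D)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shells import ShellTable

__all__ = [
    "CellGeometry",
    "LQParams",
    "EnhancementIntegrals",
    "solid_angle_in_ball",
    "omega_nucleus",
    "omega_cytoplasm",
    "omega_target",
    "compute_integrals",
    "lethal_lesions",
    "dose_enhancement_factor",
    "PLACEMENT_PRESETS_NM",
]

# Cluster-centre distances (nm) used for the standard placement study:
# just outside the nucleus, mid-cytoplasm, just inside the cell membrane,
# and outside the cell.
PLACEMENT_PRESETS_NM = (7500.0, 11000.0, 14500.0, 26000.0)


@dataclass(frozen=True)
class CellGeometry:
    """Concentric spherical nucleus/cell with a cluster at distance ``d``."""

    nucleus_radius: float = 7000.0
    cell_radius: float = 15000.0
    cluster_distance: float = 7500.0
    cluster_radius: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise ValueError("need 0 < nucleus radius < cell radius")
        if self.cluster_distance < 0:
            raise ValueError("cluster distance must be >= 0")
        if self.cluster_radius < 0:
            raise ValueError("cluster radius must be >= 0")


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity with a sensitive volume (nm^3)."""

    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2
    dose: float  # Gy
    sensitive_volume: float  # nm^3

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.dose < 0:
            raise ValueError("alpha, beta and dose must be >= 0")
        if self.sensitive_volume <= 0:
            raise ValueError("sensitive volume must be > 0")


@dataclass(frozen=True)
class EnhancementIntegrals:
    """Extra dose (I1) and dose-squared (I2) in the target, nm^3."""

    I1: float
    I2: float

    def __post_init__(self) -> None:
        if self.I1 < 0 or self.I2 < 0:
            raise ValueError("integrals must be >= 0")


def solid_angle_in_ball(r, d: float, ball_radius: float):
    """Solid angle of the sphere of radius ``r`` lying inside a ball.

    The sphere is centred at distance ``d`` from the centre of a ball of
    radius ``R``.  Piecewise: 4 pi when the sphere is entirely inside
    (d + r <= R), 0 when disjoint (r >= d + R or d >= r + R), otherwise
    the spherical cap 2 pi (1 - cos(theta)) with
    cos(theta) = (d^2 + r^2 - R^2) / (2 d r).  Continuous in ``r``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r <= 0):
        raise ValueError("sphere radius must be > 0")
    R = ball_radius
    if d == 0.0:
        omega = np.where(r <= R, 4.0 * np.pi, 0.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (d * d + r * r - R * R) / (2.0 * d * r)
        c = np.clip(c, -1.0, 1.0)
        omega = 2.0 * np.pi * (1.0 - c)
    return float(omega[0]) if scalar else omega


def omega_nucleus(r, geom: CellGeometry):
    return solid_angle_in_ball(r, geom.cluster_distance, geom.nucleus_radius)


def omega_cytoplasm(r, geom: CellGeometry):
    """Solid angle inside the cell but outside the nucleus."""
    return solid_angle_in_ball(r, geom.cluster_distance, geom.cell_radius) - omega_nucleus(r, geom)


def omega_target(r, geom: CellGeometry, target: str):
    if target == "nucleus":
        return omega_nucleus(r, geom)
    if target == "cytoplasm":
        return omega_cytoplasm(r, geom)
    if target == "cell":
        return solid_angle_in_ball(r, geom.cluster_distance, geom.cell_radius)
    raise ValueError(f"unknown target {target!r}; use nucleus, cytoplasm or cell")


def compute_integrals(
    shells: ShellTable,
    geom: CellGeometry,
    target: str = "nucleus",
    include_cluster_interior: bool = False,
) -> EnhancementIntegrals:
    """Trapezoidal quadrature of S(r) Omega(r)/(4 pi) over the target range.

    The radial domain runs from the cluster radius (the cluster interior
    is taken as biologically inert; set ``include_cluster_interior`` to
    integrate from r = 0 instead) out to ``d + R_target``, beyond which
    Omega vanishes.  The shell table must cover that range; endpoint
    values are linearly interpolated onto the exact domain limits.
    """
    # the grid always spans out to d + r_cell regardless of target (Omega of
    # a smaller target vanishes beyond its own reach), so integrals over
    # nucleus, cytoplasm and whole cell share one quadrature grid and are
    # exactly additive
    r_lo = 0.0 if include_cluster_interior else geom.cluster_radius
    r_hi = geom.cluster_distance + geom.cell_radius

    radii = shells.radii
    if radii[-1] < r_hi:
        raise ValueError(
            f"shell table ends at {radii[-1]:g} nm but the target extends to "
            f"{r_hi:g} nm; missing range [{radii[-1]:g}, {r_hi:g}] nm"
        )
    if r_lo > 0 and radii[0] > r_lo:
        raise ValueError(
            f"shell table starts at {radii[0]:g} nm but the integration domain "
            f"starts at {r_lo:g} nm; missing range [{r_lo:g}, {radii[0]:g}] nm"
        )
    # Omega is only piecewise smooth (kinked at the contact radii of each
    # target ball, a sharp step when d = 0), so the quadrature is split at
    # those breakpoints and each smooth piece integrated separately
    r_start = max(r_lo, radii[0])
    d = geom.cluster_distance
    breaks = {r_start, r_hi}
    for R in (geom.nucleus_radius, geom.cell_radius):
        for b in (abs(d - R), d + R):
            if r_start < b < r_hi:
                breaks.add(b)
    edges = np.array(sorted(breaks))
    I1 = I2 = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        eps = 1e-9 * (hi - lo)
        interior = radii[(radii > lo + eps) & (radii < hi - eps)]
        grid = np.concatenate([[lo + eps], interior, [hi - eps]])
        S1 = np.interp(grid, radii, shells.S1)
        S2 = np.interp(grid, radii, shells.S2)
        w = omega_target(grid, geom, target) / (4.0 * np.pi)
        I1 += float(np.trapezoid(S1 * w, grid))
        I2 += float(np.trapezoid(S2 * w, grid))
    return EnhancementIntegrals(max(I1, 0.0), max(I2, 0.0))


def lethal_lesions(lq: LQParams, integrals: EnhancementIntegrals) -> float:
    """Expected lethal-lesion count for one cluster in a uniform dose.

    ``alpha D + beta D^2 + (alpha D I1 + beta D I2 + 2 beta D^2 I1) / V_sens``.
    """
    a, b, D, V = lq.alpha, lq.beta, lq.dose, lq.sensitive_volume
    I1, I2 = integrals.I1, integrals.I2
    return a * D + b * D**2 + (a * D * I1 + b * D * I2 + 2 * b * D**2 * I1) / V


def dose_enhancement_factor(lq: LQParams, I1: float) -> float:
    """Relative increase in lethal lesions due to the cluster, I2 neglected.

    ``DEF = I1 (alpha + 2 beta D) / (V_sens (alpha + beta D))``; I2 is
    dropped because it is far smaller than I1 in practice.
    """
    a, b, D, V = lq.alpha, lq.beta, lq.dose, lq.sensitive_volume
    denom = a + b * D
    if denom == 0:
        raise ValueError("alpha + beta*D must be > 0 (alpha = beta = 0 is undefined)")
    return I1 * (a + 2 * b * D) / (V * denom)
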