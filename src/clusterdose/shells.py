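"""Spherical-surface statistics of the local enhancement field.

For a sphere of radius ``r`` centred on the cluster,

    S1(r) = integral over the sphere of L dA,
    S2(r) = integral over the sphere of L^2 dA,

estimated as the equal-weight average of L (and L^2) over a deterministic
Vogel spiral of points on the sphere, multiplied by the sphere area
4 pi r^2.  ``S1(r) dr`` is the extra energy deposited in a thin shell
(volume units at unit background dose); ``S1/(4 pi r^2)`` is the surface
average <L>.  These radial profiles are the inputs to the sensitive-volume
integrals of the cell model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .activation import ActivationSet
from .cluster import Cluster
from .dose_field import TransportConfig, local_enhancement
from .kernels import RadialBinning, RDDKernel

__all__ = ["ShellTable", "vogel_sphere_points", "shell_statistics", "shell_profile"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def vogel_sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (Vogel/Fibonacci spiral).

    Heights ``z`` are uniformly spaced in (-1, 1) and the azimuth advances
    by the golden angle between consecutive points; deterministic.
    """
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n)
    z = -1.0 + 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class ShellTable:
    """Radial profiles of S1, S2 (nm^2) and the surface average of L."""

    radii: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    mean_L: np.ndarray
    bin_widths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.S1 = np.asarray(self.S1, dtype=float)
        self.S2 = np.asarray(self.S2, dtype=float)
        self.mean_L = np.asarray(self.mean_L, dtype=float)
        if not (self.radii.shape == self.S1.shape == self.S2.shape == self.mean_L.shape):
            raise ValueError("shell table columns must align")
        if self.bin_widths is not None:
            self.bin_widths = np.asarray(self.bin_widths, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "radius_nm": self.radii,
            "S1_nm2": self.S1,
            "S2_nm2": self.S2,
            "mean_L": self.mean_L,
        }
        if self.bin_widths is not None:
            data["dr_nm"] = self.bin_widths
        return pd.DataFrame(data)


def shell_statistics(
    activations: ActivationSet,
    cluster: Cluster,
    kernel: RDDKernel,
    r: float,
    cfg: TransportConfig,
    n_points: int = 1000,
    evaluator: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """(S1, S2, <L>) on the sphere of radius ``r`` centred on the cluster.

    The surface quadrature is the equal-weight average over ``n_points``
    Vogel points.  ``evaluator`` may replace the kernel-superposition
    field (mainly for testing against analytic fields).
    """
    if r <= 0:
        raise ValueError("shell radius must be > 0")
    pts = r * vogel_sphere_points(n_points)
    if evaluator is None:
        L = local_enhancement(activations, cluster, kernel, pts, cfg)
    else:
        L = np.asarray(evaluator(pts), dtype=float)
        if L.shape == ():
            L = np.full(n_points, float(L))
    area = 4.0 * np.pi * r * r
    mean_L = float(np.mean(L))
    return area * mean_L, area * float(np.mean(L**2)), mean_L


def shell_profile(
    activations: ActivationSet,
    cluster: Cluster,
    kernel: RDDKernel,
    binning: RadialBinning,
    cfg: TransportConfig,
    n_points: int = 1000,
    r_max: float | None = None,
) -> ShellTable:
    """Shell statistics at the binning's representative radii.

    Radii run from the first bin out to ``r_max`` (default: cluster radius
    plus the kernel support, beyond which the field is identically zero),
    including radii inside the cluster.
    """
    if r_max is None:
        r_max = cluster.cluster_radius + kernel.support_radius
    rep = binning.representative_radii
    widths = binning.widths
    # keep every representative radius up to r_max, plus one beyond so that
    # downstream quadratures can interpolate across r_max itself
    n_keep = int(np.searchsorted(rep, r_max, side="right"))
    n_keep = min(max(n_keep + 1, 1), rep.size)
    radii = rep[:n_keep]
    widths = widths[:n_keep]
    S1 = np.zeros_like(radii)
    S2 = np.zeros_like(radii)
    mL = np.zeros_like(radii)
    directions = vogel_sphere_points(n_points)
    for j, r in enumerate(radii):
        pts = r * directions
        L = local_enhancement(activations, cluster, kernel, pts, cfg)
        area = 4.0 * np.pi * r * r
        mL[j] = np.mean(L)
        S1[j] = area * mL[j]
        S2[j] = area * np.mean(L**2)
    return ShellTable(radii, S1, S2, mL, widths)
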