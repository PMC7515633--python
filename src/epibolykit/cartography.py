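"""Spherical embryo cartography: alignment, unwrapping, density, epiboly %.

The embryo point cloud is rigidly aligned so that its centre sits at
the origin and the vegetal pole on the positive y-axis, then converted
to spherical coordinates (azimuth in [-pi, pi], elevation in
[-pi/2, pi/2]); plotting azimuth against elevation "unwraps" the
embryo into a 2D map.  Local cell density is the number of nuclei
(self included) inside a 40 µm bounding sphere centred on each nucleus.
Epiboly percentage is the axial extent of the blastoderm from the
animal pole, as measured on lateral-view micrographs: the projection
of the margin onto the animal–vegetal (AV) axis divided by the full
pole-to-pole distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_DENSITY_RADIUS = 40.0  # µm bounding sphere of the density count


@dataclass
class EmbryoAxes:
    """Embryo centre and pole landmarks (µm)."""

    center: np.ndarray
    animal_pole: np.ndarray
    vegetal_pole: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.animal_pole = np.asarray(self.animal_pole, dtype=float)
        self.vegetal_pole = np.asarray(self.vegetal_pole, dtype=float)
        if np.allclose(self.animal_pole, self.vegetal_pole):
            raise ValueError("animal and vegetal poles must be distinct")

    @property
    def av_axis(self) -> np.ndarray:
        """Unit vector from the animal to the vegetal pole."""
        v = self.vegetal_pole - self.animal_pole
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("degenerate AV axis")
        return v / n


def alignment_transform(axes: EmbryoAxes) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation mapping the embryo to canonical pose.

    After applying ``p' = R @ (p - center)`` the vegetal pole lies on
    the positive y-axis.  The rotation is the minimal one (Rodrigues
    formula about the common normal); the roll about the AV axis is
    left unconstrained.
    """
    v = axes.vegetal_pole - axes.center
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("vegetal pole coincides with the centre")
    v = v / norm
    target = np.array([0.0, 1.0, 0.0])
    c = float(np.dot(v, target))
    if c > 1 - 1e-12:
        rot = np.eye(3)
    elif c < -1 + 1e-12:
        rot = np.diag([1.0, -1.0, -1.0])  # 180° about x
    else:
        axis = np.cross(v, target)
        s = np.linalg.norm(axis)
        axis = axis / s
        k = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        rot = np.eye(3) + s * k + (1 - c) * (k @ k)
    return rot, axes.center


def align_embryo(points: np.ndarray, axes: EmbryoAxes) -> np.ndarray:
    """Rigidly transform points so the vegetal pole lies on +y."""
    rot, center = alignment_transform(axes)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - center) @ rot.T


def to_spherical(points: np.ndarray) -> pd.DataFrame:
    """Cartesian (aligned) to spherical: azimuth, elevation, radius.

    With the AV axis on y: elevation = arcsin(y / r) so the vegetal
    pole maps to +pi/2; azimuth = atan2(z, x).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    with np.errstate(invalid="ignore"):
        elevation = np.arcsin(np.clip(pts[:, 1] / np.where(r == 0, 1.0, r), -1, 1))
    elevation = np.where(r == 0, 0.0, elevation)
    azimuth = np.arctan2(pts[:, 2], pts[:, 0])
    return pd.DataFrame({"azimuth": azimuth, "elevation": elevation, "radius_um": r})


def from_spherical(sph: pd.DataFrame) -> np.ndarray:
    """Inverse of :func:`to_spherical` (columns azimuth, elevation, radius_um)."""
    az = sph["azimuth"].to_numpy(dtype=float)
    el = sph["elevation"].to_numpy(dtype=float)
    r = sph["radius_um"].to_numpy(dtype=float)
    x = r * np.cos(el) * np.cos(az)
    z = r * np.cos(el) * np.sin(az)
    y = r * np.sin(el)
    return np.column_stack([x, y, z])


def local_density(
    points: np.ndarray, radius_um: float = DEFAULT_DENSITY_RADIUS
) -> np.ndarray:
    """Neighbour count (self included) within ``radius_um`` of each point.

    Uses a k-d tree for point clouds larger than 1000 and brute-force
    pairwise distances otherwise; both give identical integer counts.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=int)
    if n > 1000:
        tree = cKDTree(pts)
        counts = tree.query_ball_point(pts, r=radius_um, return_length=True)
        return np.asarray(counts, dtype=int)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return (d <= radius_um).sum(axis=1).astype(int)


def density_table(
    nuclei: pd.DataFrame, radius_um: float = DEFAULT_DENSITY_RADIUS
) -> pd.DataFrame:
    """Per-nucleus density table with spherical coordinates attached."""
    pts = nuclei[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    sph = to_spherical(pts)
    out = pd.DataFrame(
        {
            "nucleus_id": nuclei["nucleus_id"].to_numpy()
            if "nucleus_id" in nuclei
            else np.arange(len(nuclei)),
            "azimuth": sph["azimuth"],
            "elevation": sph["elevation"],
            "radius_um": sph["radius_um"],
            "count": local_density(pts, radius_um),
        }
    )
    return out


def unwrap_density(
    per_nucleus: pd.DataFrame,
    n_azimuth: int = 36,
    n_elevation: int = 18,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid the per-nucleus densities on an azimuth × elevation map.

    Returns ``(grid, azimuth_edges, elevation_edges)`` where grid holds
    the mean neighbour count per bin and NaN marks empty bins (distinct
    from a measured zero).  Azimuth spans [-pi, pi] on the first axis
    of the plot (x), elevation [-pi/2, pi/2] on the second (y); the
    returned array is indexed ``grid[i_azimuth, j_elevation]``.
    """
    az_edges = np.linspace(-np.pi, np.pi, n_azimuth + 1)
    el_edges = np.linspace(-np.pi / 2, np.pi / 2, n_elevation + 1)
    from scipy.stats import binned_statistic_2d

    if len(per_nucleus) == 0:
        return np.full((n_azimuth, n_elevation), np.nan), az_edges, el_edges
    stat, _, _, _ = binned_statistic_2d(
        per_nucleus["azimuth"],
        per_nucleus["elevation"],
        per_nucleus["count"],
        statistic="mean",
        bins=[az_edges, el_edges],
    )
    return stat, az_edges, el_edges


def epiboly_percentage(axes: EmbryoAxes, margin_point: np.ndarray) -> float:
    """Epiboly progress: axial animal-to-margin extent over the AV length.

    100 × (projection of margin − animal pole on the AV axis) divided
    by the pole-to-pole distance, clamped to [0, 100].
    """
    margin = np.asarray(margin_point, dtype=float)
    av = axes.vegetal_pole - axes.animal_pole
    length = float(np.linalg.norm(av))
    if length == 0:
        raise ValueError("animal and vegetal poles coincide")
    f = float(np.dot(margin - axes.animal_pole, av / length)) / length
    return 100.0 * float(np.clip(f, 0.0, 1.0))
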