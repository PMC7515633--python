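"""Synthetic 4D embryo generator.

Emulates the nuclei of a zebrafish blastoderm during epiboly as a point
process on a thin spherical shell: an origin-centred embryo with the
vegetal pole on the positive y-axis, a blastoderm cap of nuclei that
spreads vegetally (the margin's polar angle advances at a configured
rate), ongoing cell divisions, and three layers (EVL / DEL / YSL) that
differ only in radial placement.  An "arrested" run freezes the vegetal
advance at ``arrest_time`` while divisions continue — the morphant-like
condition in which cell density rises because spreading stops.

A companion renderer turns per-frame nucleus tables into anisotropic
image stacks (Gaussian blobs + Poisson–Gaussian noise) so that the
detection stage can be exercised against known ground truth.

Units: µm and minutes throughout.  Polar angle is measured from the
animal pole, in degrees, so the margin at 90° corresponds to 50%
epiboly and 180° to completion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SimulationConfig:
    """Parameters of the ground-truth epiboly simulation.

    Defaults are a desk-scale embryo (radius 120 µm, ≤ a few hundred
    nuclei, tens of frames) rather than the ~350 µm, 10–15 h original;
    the geometry and kinematics scale linearly.
    """

    embryo_radius: float = 120.0  # µm
    shell_thickness: float = 15.0  # µm; blastoderm depth
    n_initial_nuclei: int = 300
    division_interval: float | None = 30.0  # min between divisions; None disables
    epiboly_start: float = 0.0  # min
    epiboly_speed: float = 0.3  # degrees of margin polar angle per min
    arrest_time: float | None = None  # min; freeze vegetal advance (morphant-like)
    n_frames: int = 40
    frame_interval: float = 1.0  # min
    initial_margin_deg: float = 75.0  # margin polar angle at t=0
    layer_fractions: tuple[float, float, float] = (0.2, 0.7, 0.1)  # EVL, DEL, YSL
    motion_noise_sd: float = 0.3  # µm per step, tangential random walk
    division_offset: float = 5.0  # µm daughter separation from division site
    min_separation: float = 0.0  # µm enforced between initial nuclei (0 = off)
    rng_seed: int = 0

    def validate(self) -> None:
        numeric = {
            "embryo_radius": self.embryo_radius,
            "shell_thickness": self.shell_thickness,
            "epiboly_speed": self.epiboly_speed,
            "frame_interval": self.frame_interval,
            "motion_noise_sd": self.motion_noise_sd,
            "initial_margin_deg": self.initial_margin_deg,
        }
        for name, v in numeric.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.embryo_radius <= 0:
            raise ValueError("embryo_radius must be > 0")
        if self.n_initial_nuclei < 0:
            raise ValueError("n_initial_nuclei must be >= 0")
        if self.epiboly_speed < 0 or self.motion_noise_sd < 0 or self.min_separation < 0:
            raise ValueError("speeds, noise levels and separations must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.division_interval is not None and self.division_interval <= 0:
            raise ValueError("division_interval must be > 0 or None")
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ValueError("layer_fractions must sum to 1")
        if not 0 < self.initial_margin_deg <= 180:
            raise ValueError("initial_margin_deg must be in (0, 180]")


LAYERS = ("EVL", "DEL", "YSL")


@dataclass
class GroundTruth:
    """Simulated nuclei with true track ids and layer labels.

    ``nuclei`` columns: frame, nucleus_id, track_id, x_um, y_um, z_um,
    layer, intensity.  ``margin_polar_angle`` is the margin's polar
    angle (degrees from the animal pole) per frame.
    """

    nuclei: pd.DataFrame
    margin_polar_angle: np.ndarray
    animal_pole: np.ndarray
    vegetal_pole: np.ndarray
    config: SimulationConfig = field(repr=False, default_factory=SimulationConfig)

    def frame(self, k: int) -> pd.DataFrame:
        return self.nuclei[self.nuclei["frame"] == k]


def _sph_to_cart(r: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Polar angle theta from the animal pole (-y); vegetal pole is +y."""
    sin_t = np.sin(theta)
    x = r * sin_t * np.cos(phi)
    z = r * sin_t * np.sin(phi)
    y = -r * np.cos(theta)
    return np.column_stack([x, y, z])


def margin_angle_schedule(config: SimulationConfig) -> np.ndarray:
    """Margin polar angle (degrees) at each frame time."""
    times = np.arange(config.n_frames) * config.frame_interval
    advance_until = times if config.arrest_time is None else np.minimum(times, config.arrest_time)
    elapsed = np.clip(advance_until - config.epiboly_start, 0.0, None)
    return np.minimum(config.initial_margin_deg + config.epiboly_speed * elapsed, 180.0)


def simulate_epiboly(config: SimulationConfig) -> GroundTruth:
    """Run the ground-truth simulation.

    Each nucleus keeps a fixed latitude fraction ``u`` (its polar angle
    divided by the margin angle at birth), so the cap stretches
    self-similarly as the margin advances: margin-adjacent nuclei
    (u ≈ 1) move vegetally at the configured ``epiboly_speed`` while
    nuclei near the animal pole barely move.  Tangential Gaussian noise
    models undirected motility.  Divisions replace a nucleus by two
    daughters (new unique ids and track ids, inherited layer) offset
    ±``division_offset``/2 along a random tangent.

    Deterministic given ``rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    margins = margin_angle_schedule(config)
    margin0 = math.radians(margins[0])
    n = config.n_initial_nuclei

    # Uniform-area sampling on the initial cap: cos(theta) uniform.
    # Radial placement by layer: EVL at the surface, DEL through the
    # shell depth, YSL at the yolk interface.
    R, h = config.embryo_radius, config.shell_thickness

    def _sample_one():
        th = math.acos(rng.uniform(math.cos(margin0), 1.0))
        ph = rng.uniform(-math.pi, math.pi)
        lay = int(rng.choice(len(LAYERS), p=list(config.layer_fractions)))
        if lay == 0:
            rr = R - 0.5
        elif lay == 1:
            rr = rng.uniform(R - h + 2.0, R - 2.0)
        else:
            rr = R - h + 0.5
        return th, ph, lay, rr

    theta = np.empty(n)
    phi = np.empty(n)
    layer = np.empty(n, dtype=int)
    r = np.empty(n)
    accepted: list[np.ndarray] = []
    for i in range(n):
        for _attempt in range(10_000):
            th, ph, lay, rr = _sample_one()
            p = _sph_to_cart(np.array([rr]), np.array([th]), np.array([ph]))[0]
            if config.min_separation <= 0 or all(
                np.linalg.norm(p - q) >= config.min_separation for q in accepted
            ):
                break
        else:
            raise ValueError(
                f"cannot place {n} nuclei with min_separation="
                f"{config.min_separation} µm on the initial cap"
            )
        theta[i], phi[i], layer[i], r[i] = th, ph, lay, rr
        accepted.append(p)
    u = theta / margin0  # latitude fraction, fixed at birth
    intensity = rng.lognormal(mean=math.log(1000.0), sigma=0.15, size=n)

    nucleus_id = np.arange(n, dtype=int)
    track_id = nucleus_id.copy()
    birth = np.zeros(n)
    next_id = n

    rows: list[pd.DataFrame] = []

    def record(k: int) -> None:
        pos = _sph_to_cart(r, theta, phi)
        rows.append(
            pd.DataFrame(
                {
                    "frame": k,
                    "nucleus_id": nucleus_id,
                    "track_id": track_id,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "z_um": pos[:, 2],
                    "layer": [LAYERS[i] for i in layer],
                    "intensity": intensity,
                }
            )
        )

    record(0)
    for k in range(1, config.n_frames):
        t_k = k * config.frame_interval
        # Vegetal advance proportional to latitude fraction.
        d_margin = math.radians(margins[k] - margins[k - 1])
        theta = theta + u * d_margin
        # Tangential random walk (converted to angular perturbations).
        if config.motion_noise_sd > 0 and len(theta) > 0:
            step = rng.normal(0.0, config.motion_noise_sd, size=(len(theta), 2))
            theta = np.clip(theta + step[:, 0] / r, 1e-6, math.pi - 1e-6)
            phi = phi + step[:, 1] / (r * np.maximum(np.sin(theta), 1e-3))
        # Divisions: nuclei whose age reached division_interval split.
        if config.division_interval is not None and len(theta) > 0:
            due = (t_k - birth) >= config.division_interval
            if np.any(due):
                idx = np.flatnonzero(due)
                m = len(idx)
                # Random tangent direction for the daughter offset.
                dphi = rng.uniform(-math.pi, math.pi, size=m)
                off_t = (config.division_offset / 2.0) * np.cos(dphi) / r[idx]
                off_p = (config.division_offset / 2.0) * np.sin(dphi) / (
                    r[idx] * np.maximum(np.sin(theta[idx]), 1e-3)
                )
                keep = ~due
                new_theta = np.concatenate(
                    [theta[keep], theta[idx] + off_t, theta[idx] - off_t]
                )
                new_phi = np.concatenate([phi[keep], phi[idx] + off_p, phi[idx] - off_p])
                new_u = np.concatenate([u[keep], u[idx], u[idx]])
                new_r = np.concatenate([r[keep], r[idx], r[idx]])
                new_layer = np.concatenate([layer[keep], layer[idx], layer[idx]])
                new_int = np.concatenate(
                    [intensity[keep], intensity[idx], intensity[idx]]
                )
                new_ids = np.arange(next_id, next_id + 2 * m, dtype=int)
                next_id += 2 * m
                nucleus_id = np.concatenate([nucleus_id[keep], new_ids])
                track_id = np.concatenate([track_id[keep], new_ids])
                birth = np.concatenate([birth[keep], np.full(2 * m, t_k)])
                theta, phi, u, r = new_theta, new_phi, new_u, new_r
                layer, intensity = new_layer, new_int
                theta = np.clip(theta, 1e-6, math.pi - 1e-6)
        record(k)

    if rows:
        nuclei = pd.concat(rows, ignore_index=True)
    else:  # pragma: no cover
        nuclei = pd.DataFrame()
    R = config.embryo_radius
    return GroundTruth(
        nuclei=nuclei,
        margin_polar_angle=margins,
        animal_pole=np.array([0.0, -R, 0.0]),
        vegetal_pole=np.array([0.0, R, 0.0]),
        config=config,
    )


def margin_fraction_to_angle(f: float) -> float:
    """Polar angle (deg) whose axial projection is a fraction f of the AV axis.

    The epiboly percentage measured on a lateral view is the axial
    (y-axis) extent from the animal pole: f = (1 - cos theta) / 2.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return math.degrees(math.acos(1.0 - 2.0 * f))


def apply_dropout(nuclei: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly delete a fraction of detections (single-frame dropouts)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    keep = rng.random(len(nuclei)) >= rate
    return nuclei[keep].reset_index(drop=True)


def constant_speed_tracks(
    n_tracks: int,
    n_steps: int,
    speed: float,
    frame_interval: float = 1.0,
    speed_jitter_sd: float = 0.0,
    heading_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list:
    """Simulated migrating cells with a set speed and wobbling heading.

    Per-step speeds are drawn from Normal(speed, speed_jitter_sd)
    (clipped at zero) so the mean step length equals ``speed`` — the
    estimand of :func:`epibolykit.tracking.estimate_mean_speed` — while
    the heading performs a random walk on the unit sphere.  ``speed``
    is in µm per minute; step length is speed × frame_interval.
    """
    from .records import Track

    rng = np.random.default_rng(0) if rng is None else rng
    tracks = []
    for tid in range(n_tracks):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = rng.uniform(-50, 50, size=3)
        positions = [pos.copy()]
        for _ in range(n_steps):
            if heading_sd > 0:
                direction = direction + rng.normal(0.0, heading_sd, size=3)
                direction /= np.linalg.norm(direction)
            s = speed
            if speed_jitter_sd > 0:
                s = max(0.0, rng.normal(speed, speed_jitter_sd))
            pos = pos + direction * s * frame_interval
            positions.append(pos.copy())
        tracks.append(
            Track(track_id=tid, frames=np.arange(n_steps + 1), positions=np.array(positions))
        )
    return tracks


@dataclass
class RenderConfig:
    """Parameters of the synthetic light-sheet renderer.

    Default spacing mirrors the acquisition geometry of the emulated
    microscope (1.5 µm lateral sampling, 2 µm axial step); the nuclear
    point-spread blob is an anisotropic Gaussian.
    """

    lateral_spacing: float = 1.5  # µm/voxel in x and y
    axial_spacing: float = 2.0  # µm/voxel in z
    psf_sigma_lateral: float = 1.8  # µm
    psf_sigma_axial: float = 2.6  # µm
    background_level: float = 100.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    amplitude_scale: float = 1.0  # multiplies nucleus intensities
    field_of_view: tuple[tuple[float, float], ...] | None = None  # ((x0,x1),(y0,y1),(z0,z1)) µm
    pad_um: float = 12.0  # FOV margin added around nuclei when auto-sized

    def validate(self) -> None:
        if self.lateral_spacing <= 0 or self.axial_spacing <= 0:
            raise ValueError("voxel spacings must be > 0")
        if self.psf_sigma_lateral <= 0 or self.psf_sigma_axial <= 0:
            raise ValueError("psf sigmas must be > 0")


def render_stack(
    nuclei_at_frame: pd.DataFrame,
    render: RenderConfig,
    rng: np.random.Generator | None = None,
):
    """Render one frame's nuclei into an anisotropic image stack.

    Each nucleus contributes an anisotropic Gaussian blob centred at
    its position; Poisson and/or Gaussian noise is applied on top of a
    constant background.  Raises if any nucleus falls outside the field
    of view (listing the offending ids).
    """
    from .records import ImageStack

    render.validate()
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(nuclei_at_frame)
    if n > 0:
        pos = nuclei_at_frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        inten = (
            nuclei_at_frame["intensity"].to_numpy(dtype=float)
            if "intensity" in nuclei_at_frame
            else np.full(n, 1000.0)
        )
        ids = (
            nuclei_at_frame["nucleus_id"].to_numpy()
            if "nucleus_id" in nuclei_at_frame
            else np.arange(n)
        )
    else:
        pos = np.zeros((0, 3))
        inten = np.zeros(0)
        ids = np.zeros(0, dtype=int)

    if render.field_of_view is not None:
        fov = np.asarray(render.field_of_view, dtype=float)  # rows: x, y, z
    elif n > 0:
        fov = np.column_stack([pos.min(axis=0) - render.pad_um, pos.max(axis=0) + render.pad_um])
    else:
        fov = np.array([[0.0, 30.0]] * 3)

    if n > 0:
        inside = np.all((pos >= fov[:, 0]) & (pos <= fov[:, 1]), axis=1)
        if not np.all(inside):
            bad = ids[~inside].tolist()
            raise ValueError(f"nuclei outside field of view: {bad}")

    spacing = np.array([render.axial_spacing, render.lateral_spacing, render.lateral_spacing])
    origin = fov[[2, 1, 0], 0]  # (z, y, x) µm of voxel (0,0,0)
    extent = fov[[2, 1, 0], 1] - origin
    shape = np.maximum(np.ceil(extent / spacing).astype(int) + 1, 1)

    vol = np.full(shape, float(render.background_level), dtype=np.float64)
    sigma_vox = np.array(
        [
            render.psf_sigma_axial / render.axial_spacing,
            render.psf_sigma_lateral / render.lateral_spacing,
            render.psf_sigma_lateral / render.lateral_spacing,
        ]
    )
    half = np.ceil(4 * sigma_vox).astype(int)
    for p, amp in zip(pos, inten):
        centre = (p[[2, 1, 0]] - origin) / spacing  # voxel coords (z, y, x)
        lo = np.maximum(np.floor(centre - half).astype(int), 0)
        hi = np.minimum(np.ceil(centre + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
        expo = sum(
            ((grids[d] - centre[d]) / sigma_vox[d]) ** 2 for d in range(3)
        )
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            amp * render.amplitude_scale * np.exp(-0.5 * expo)
        )

    if render.poisson_noise:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(np.float64)
    if render.gaussian_noise_sd > 0:
        vol = vol + rng.normal(0.0, render.gaussian_noise_sd, size=vol.shape)

    return ImageStack(data=vol, spacing=tuple(spacing), origin=tuple(origin))
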