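"""Core in-memory containers shared across the pipeline.

All physical quantities use micrometres (µm) for space and minutes for
time.  Nucleus tables are plain :class:`pandas.DataFrame` objects with a
documented schema (one row per nucleus per frame), which keeps every
stage composable with standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a nucleus table (one detected or simulated nucleus
#: at one time point).  Simulated tables additionally carry ``track_id``
#: and ``layer`` ground-truth columns; detection tables carry feature
#: columns (``intensity_integrated``, ``radius_um``, ``border_um``).
NUCLEUS_COLUMNS = ["frame", "nucleus_id", "x_um", "y_um", "z_um", "intensity"]

#: Columns of a track table (long format, one row per track per frame).
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "z_um", "flag", "provenance"]

#: Columns of a per-nucleus density table.
DENSITY_COLUMNS = ["nucleus_id", "azimuth", "elevation", "radius_um", "count"]

#: Columns of a phenotype count table.
COUNT_COLUMNS = ["group", "unaffected", "affected", "dead", "denominator"]


@dataclass
class ImageStack:
    """A 3D intensity volume with anisotropic voxel spacing.

    Parameters
    ----------
    data
        Volume in ``(z, y, x)`` axis order.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in µm.  Light-sheet stacks are
        typically anisotropic (e.g. 2 µm axial vs 1.5 µm lateral).
    origin
        Physical position in µm of the centre of voxel ``(0, 0, 0)``,
        in ``(z, y, x)`` order.  Defaults to the origin.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_physical(self, zyx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices ``(z, y, x)`` to µm."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        return zyx * np.array(self.spacing) + np.array(self.origin)


def empty_nucleus_table(extra: tuple[str, ...] = ()) -> pd.DataFrame:
    cols = NUCLEUS_COLUMNS + list(extra)
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["frame"] = df["frame"].astype(int)
    df["nucleus_id"] = df["nucleus_id"].astype(int)
    return df


def validate_nucleus_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the nucleus-table schema; raise ``ValueError`` naming missing columns."""
    missing = [c for c in NUCLEUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"nucleus table missing required columns: {missing}")
    return df


@dataclass
class Track:
    """One nucleus lineage segment: ordered per-frame positions.

    ``flags`` mark each entry as ``"observed"`` or ``"interpolated"``
    (inserted during gap repair / sub-track fusion).  ``provenance``
    lists the ids of source sub-tracks fused into this track.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray  # (n, 3) in µm, columns x, y, z
    flags: list[str] = field(default_factory=list)
    provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not self.flags:
            self.flags = ["observed"] * len(self.frames)
        if len(self.frames) != len(self.positions) or len(self.frames) != len(self.flags):
            raise ValueError("frames, positions and flags must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    def has_gaps(self) -> bool:
        return len(self.frames) > 1 and bool(np.any(np.diff(self.frames) != 1))

    def observed_mask(self) -> np.ndarray:
        return np.array([f == "observed" for f in self.flags])


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format track table (one row per track per frame)."""
    rows = []
    for t in tracks:
        prov = ";".join(str(p) for p in t.provenance) if t.provenance else ""
        for i in range(len(t)):
            rows.append(
                (t.track_id, int(t.frames[i]), *t.positions[i], t.flags[i], prov)
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df


def table_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        prov_field = sub["provenance"].iloc[0] if "provenance" in sub else ""
        provenance = (
            [int(p) for p in str(prov_field).split(";") if p not in ("", "nan")]
            if isinstance(prov_field, str) and prov_field
            else []
        )
        flags = list(sub["flag"]) if "flag" in sub else ["observed"] * len(sub)
        tracks.append(
            Track(
                track_id=int(tid),
                frames=sub["frame"].to_numpy(),
                positions=sub[["x_um", "y_um", "z_um"]].to_numpy(),
                flags=flags,
                provenance=provenance,
            )
        )
    return tracks
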