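"""Nucleus extraction from 3D stacks and detection post-processing.

The detector is a multiscale Laplacian-of-Gaussian blob finder run on a
volume resampled to isotropic µm, followed by intensity-weighted
sub-voxel centroid refinement.  Post-processing mirrors the pipeline
contract of the emulated study: fusion of redundant detections from
complementary (pre-registered) views by mutual-nearest-neighbour
pairing, feature-based rejection of false positives, and per-frame
counting of the surviving objects.

All positions are physical µm (voxel index × spacing + origin); all
distance thresholds are µm so that anisotropic sampling never distorts
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import blob_log

from .records import ImageStack

#: Features populated on every detection record, usable in rejection rules.
FEATURES = ("intensity", "intensity_integrated", "radius_um", "border_um")


@dataclass
class DetectionParams:
    """Blob-detection and post-processing parameters (all lengths µm)."""

    min_blob_sigma: float = 1.5
    max_blob_sigma: float = 4.0
    intensity_threshold: float = 0.1  # on the background-normalised scale
    fusion_radius: float = 5.0
    num_sigma: int = 4
    #: (feature, min, max) — detections outside [min, max] on any rule
    #: are rejected; use None for an open bound.
    rejection_rules: list[tuple[str, float | None, float | None]] = field(
        default_factory=list
    )

    def validate(self) -> None:
        if self.min_blob_sigma <= 0 or self.max_blob_sigma < self.min_blob_sigma:
            raise ValueError("require 0 < min_blob_sigma <= max_blob_sigma")
        if self.fusion_radius < 0:
            raise ValueError("fusion_radius must be >= 0")


def _resample_isotropic(stack: ImageStack) -> tuple[np.ndarray, float]:
    """Linear resampling of the volume to the finest spacing present."""
    iso = min(stack.spacing)
    factors = np.array(stack.spacing) / iso
    if np.allclose(factors, 1.0):
        return np.asarray(stack.data, dtype=float), iso
    vol = ndimage.zoom(np.asarray(stack.data, dtype=float), factors, order=1)
    return vol, iso


def detect_nuclei(
    stack: ImageStack, params: DetectionParams, frame: int = 0
) -> pd.DataFrame:
    """Extract candidate nucleus centroids from one stack.

    Returns a nucleus table in physical µm with per-candidate features:
    peak intensity above background, integrated intensity, a radius
    estimate (sigma·sqrt(3) of the best-responding scale) and distance
    to the nearest volume border.
    """
    params.validate()
    if stack.spacing is None or any(s <= 0 for s in stack.spacing):
        raise ValueError("stack must carry positive voxel spacing metadata")

    vol, iso = _resample_isotropic(stack)
    background = float(np.median(vol))
    peak = float(vol.max())
    scale = peak - background
    # Guard against signal-free stacks: the brightest voxel must clear
    # the noise floor (robust sd via MAD), else normalising would
    # stretch pure noise to full scale.
    noise_sd = 1.4826 * float(np.median(np.abs(vol - background)))
    if scale <= 0 or scale < 6.0 * noise_sd:
        return _empty_detection_table()
    norm = (vol - background) / scale

    blobs = blob_log(
        norm,
        min_sigma=params.min_blob_sigma / iso,
        max_sigma=params.max_blob_sigma / iso,
        num_sigma=params.num_sigma,
        threshold=params.intensity_threshold * 0.3,
    )
    if len(blobs) == 0:
        return _empty_detection_table()

    records = []
    shape = np.array(vol.shape)
    for zc, yc, xc, sigma in blobs:
        c = np.array([zc, yc, xc])
        # Sub-voxel refinement: intensity-weighted centroid in a window
        # of ±2 sigma around the LoG maximum, above half the local peak.
        half = max(int(np.ceil(2 * sigma)), 2)
        lo = np.maximum(c.astype(int) - half, 0)
        hi = np.minimum(c.astype(int) + half + 1, shape)
        win = norm[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        w = np.clip(win - 0.25 * win.max(), 0, None)
        if w.sum() > 0:
            grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
            c = np.array([float((g * w).sum() / w.sum()) for g in grids])
        peak_val = float(win.max()) if win.size else 0.0
        if peak_val < params.intensity_threshold:
            continue
        integrated = float(np.clip(win, 0, None).sum()) * scale
        border_vox = float(np.min(np.minimum(c, shape - 1 - c)))
        records.append(
            {
                "z_vox": c[0],
                "y_vox": c[1],
                "x_vox": c[2],
                "intensity": peak_val * scale,
                "intensity_integrated": integrated,
                "radius_um": float(sigma) * np.sqrt(3) * iso,
                "border_um": border_vox * iso,
            }
        )
    if not records:
        return _empty_detection_table()
    df = pd.DataFrame(records)
    origin = np.array(stack.origin)  # (z, y, x)
    df["x_um"] = df.pop("x_vox") * iso + origin[2]
    df["y_um"] = df.pop("y_vox") * iso + origin[1]
    df["z_um"] = df.pop("z_vox") * iso + origin[0]
    df.insert(0, "frame", frame)
    df.insert(1, "nucleus_id", np.arange(len(df)))
    cols = ["frame", "nucleus_id", "x_um", "y_um", "z_um", "intensity",
            "intensity_integrated", "radius_um", "border_um"]
    return df[cols].reset_index(drop=True)


def _empty_detection_table() -> pd.DataFrame:
    cols = ["frame", "nucleus_id", "x_um", "y_um", "z_um", "intensity",
            "intensity_integrated", "radius_um", "border_um"]
    df = pd.DataFrame({c: [] for c in cols})
    df["frame"] = df["frame"].astype(int)
    df["nucleus_id"] = df["nucleus_id"].astype(int)
    return df


def fuse_redundant(
    view_a: pd.DataFrame, view_b: pd.DataFrame, fusion_radius: float
) -> pd.DataFrame:
    """Fuse redundant detections from two pre-registered views.

    Mutually nearest pairs within ``fusion_radius`` are merged into one
    record at the intensity-weighted mean position; unpaired records
    pass through unchanged, so the output size is
    ``|A| + |B| - n_merged``.  The operation is symmetric in its
    arguments (the merged position set does not depend on order).
    """
    if fusion_radius < 0:
        raise ValueError("fusion_radius must be >= 0")
    if len(view_a) == 0 or len(view_b) == 0 or fusion_radius == 0:
        return pd.concat([view_a, view_b], ignore_index=True)

    pa = view_a[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    pb = view_b[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    d_ab, nn_ab = tree_b.query(pa, k=1)
    d_ba, nn_ba = tree_a.query(pb, k=1)

    ia = view_a["intensity"].to_numpy(dtype=float) if "intensity" in view_a else np.ones(len(pa))
    ib = view_b["intensity"].to_numpy(dtype=float) if "intensity" in view_b else np.ones(len(pb))

    merged_rows = []
    used_a = np.zeros(len(pa), dtype=bool)
    used_b = np.zeros(len(pb), dtype=bool)
    for i in range(len(pa)):
        j = nn_ab[i]
        if d_ab[i] <= fusion_radius and nn_ba[j] == i and d_ba[j] <= fusion_radius:
            wa, wb = ia[i], ib[j]
            tot = wa + wb if (wa + wb) > 0 else 1.0
            row = view_a.iloc[i].copy()
            row[["x_um", "y_um", "z_um"]] = (wa * pa[i] + wb * pb[j]) / tot
            if "intensity" in view_a:
                row["intensity"] = 0.5 * (wa + wb)
            merged_rows.append(row)
            used_a[i] = used_b[j] = True
    parts = [view_a[~used_a], view_b[~used_b]]
    if merged_rows:
        parts.insert(0, pd.DataFrame(merged_rows))
    out = pd.concat(parts, ignore_index=True)
    out["nucleus_id"] = np.arange(len(out))
    return out


def reject_false_positives(
    records: pd.DataFrame,
    rules: list[tuple[str, float | None, float | None]],
) -> pd.DataFrame:
    """Drop records failing any (feature, min, max) rule; order preserved."""
    if not rules:
        return records
    keep = np.ones(len(records), dtype=bool)
    for feature, lo, hi in rules:
        if feature not in records.columns:
            raise ValueError(
                f"rejection rule references absent feature {feature!r}; "
                f"available: {sorted(records.columns)}"
            )
        vals = records[feature].to_numpy(dtype=float)
        if lo is not None:
            keep &= vals >= lo
        if hi is not None:
            keep &= vals <= hi
    return records[keep].reset_index(drop=True)


def count_nuclei(records: pd.DataFrame) -> pd.Series:
    """Nucleus count per frame after fusion and rejection."""
    if len(records) == 0:
        return pd.Series(dtype=int, name="count")
    counts = records.groupby("frame").size()
    counts.name = "count"
    return counts
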