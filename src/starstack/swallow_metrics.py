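"""Quantitative swallowing parameters from an image series plus annotations.

The five real-time metrics:

* duration (s)                — frames from the last stationary motion state
                                until the oral tract first returns to it,
                                additional clearing swallows excluded;
* bolus area (cm^2)           — delineated bolus in the middle slice at rest;
* bolus volume (cm^3)         — delineated bolus over all slices at rest;
* laryngeal elevation (mm)    — largest displacement of the most inferior
                                thyroid point from its pre-swallow position;
* submental contraction (%)   — change of the mandible-to-hyoid distance at
                                its minimum relative to rest (negative =
                                shortening).

Measurements operate on landmark tracks and bolus masks — in the study these
come from a human rater; here they come from phantom ground truth or from
the template-matching tracker (`track_landmarks`, `segment_bolus`), a
validation utility for phantom reconstructions, not a clinical segmenter.
All metrics are invariant to global intensity scaling by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import (binary_closing, binary_opening, gaussian_filter,
                           label, median_filter)
from skimage.feature import match_template

from .phantom import PhantomScene

__all__ = [
    "LandmarkTrack",
    "SwallowMetrics",
    "bolus_area_volume",
    "laryngeal_elevation",
    "submental_contraction",
    "swallow_duration",
    "compute_metrics",
    "track_from_ground_truth",
    "track_landmarks",
    "segment_bolus",
]


@dataclass
class LandmarkTrack:
    """Per-frame landmark positions (mm, (y, x[, z]) relative to the volume
    centre), bolus masks and motion-state flags."""

    positions: dict  # name -> (T, 2 or 3) array, NaN rows where missing
    bolus_masks: Optional[np.ndarray]  # (T, nz, ny, nx) bool
    stationary: np.ndarray  # (T,) bool
    frame_rate: float
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 6.0)

    @property
    def n_frames(self) -> int:
        return len(self.stationary)

    def swallow_frames(self) -> np.ndarray:
        """Indices of the first contiguous moving interval."""
        moving = ~self.stationary
        if not moving.any():
            return np.array([], dtype=int)
        start = int(np.argmax(moving))
        after = np.nonzero(~moving[start:])[0]
        stop = start + (int(after[0]) if len(after) else len(moving) - start)
        return np.arange(start, stop)

    def reference_frame(self) -> int:
        """Last stationary frame before the swallow (frame 0 if none)."""
        sw = self.swallow_frames()
        return max(int(sw[0]) - 1, 0) if len(sw) else 0

    def rest_frames(self) -> np.ndarray:
        """Pre-swallow stationary frames (up to the reference frame)."""
        return np.arange(self.reference_frame() + 1)


@dataclass
class SwallowMetrics:
    duration_s: float
    bolus_area_cm2: float
    bolus_volume_cm3: float
    laryngeal_elevation_mm: float
    submental_contraction_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [
                    self.duration_s,
                    self.bolus_area_cm2,
                    self.bolus_volume_cm3,
                    self.laryngeal_elevation_mm,
                    self.submental_contraction_pct,
                ]
            },
            index=[
                "Duration (s)",
                "Bolus (cm2)",
                "Bolus (cm3)",
                "Laryngeal elevation (mm)",
                "Contraction of submental muscles (%)",
            ],
        )


def bolus_area_volume(
    masks: np.ndarray,
    voxel_size: tuple[float, float, float],
    middle_slice: int,
    rest_frame: int = 0,
) -> tuple[float, float]:
    """Bolus area (cm^2, middle slice) and volume (cm^3, all slices) at the
    rest frame before swallow onset."""
    m = np.asarray(masks[rest_frame], bool)
    vy, vx, vz = voxel_size
    if not m.any():
        warnings.warn("empty bolus mask; area and volume are zero")
        return 0.0, 0.0
    area = float(m[middle_slice].sum()) * (vy * vx) / 100.0
    volume = float(m.sum()) * (vy * vx * vz) / 1000.0
    return area, volume


def laryngeal_elevation(track: LandmarkTrack) -> float:
    """Largest displacement (mm) of the most inferior thyroid point during
    the swallow relative to its pre-swallow position."""
    pos = np.asarray(track.positions["most_inferior_thyroid"], float)
    sw = track.swallow_frames()
    frames = sw if len(sw) else np.arange(track.n_frames)
    rest = track.rest_frames()
    if np.isnan(pos[frames]).any() or np.isnan(pos[rest]).any():
        raise ValueError("missing thyroid landmark in required frames")
    # median over the pre-swallow rest frames suppresses annotation jitter;
    # identical to the single-frame reference when the rest pose is static
    ref = np.median(pos[rest], axis=0)
    return float(np.linalg.norm(pos[frames] - ref, axis=1).max())


def submental_contraction(track: LandmarkTrack) -> float:
    """Submental length change (%) at its swallow minimum relative to rest;
    negative values mean contraction."""
    mand = np.asarray(track.positions["mandible_right_edge"], float)
    hyoid = np.asarray(track.positions["hyoid_left_edge"], float)
    lengths = np.linalg.norm(hyoid - mand, axis=1)
    rest = float(np.median(lengths[track.rest_frames()]))
    if not np.isfinite(rest) or rest == 0:
        raise ValueError("zero or undefined rest submental length")
    sw = track.swallow_frames()
    frames = sw if len(sw) else np.arange(track.n_frames)
    extremum = lengths[frames][np.abs(lengths[frames] - rest).argmax()]
    return float(100.0 * (extremum - rest) / rest)


def swallow_duration(stationary: np.ndarray, frame_rate: float) -> float:
    """Duration (s) of the first swallow: moving-frame count / frame rate.

    Counts frames strictly between the last pre-swallow stationary frame and
    the first return to stationary; later clearing swallows are excluded.
    If motion never returns to stationary the duration runs to the series
    end, with a warning.
    """
    stationary = np.asarray(stationary, bool)
    moving = ~stationary
    if not moving.any():
        return 0.0
    start = int(np.argmax(moving))
    after = np.nonzero(~moving[start:])[0]
    if len(after) == 0:
        warnings.warn("oral tract never returns to the stationary state; "
                      "duration measured to the series end")
        n_moving = len(moving) - start
    else:
        n_moving = int(after[0])
    return n_moving / frame_rate


def compute_metrics(track: LandmarkTrack, middle_slice: int) -> SwallowMetrics:
    """All five swallowing metrics from one annotated series."""
    area, volume = bolus_area_volume(
        track.bolus_masks, track.voxel_size, middle_slice,
        rest_frame=track.reference_frame(),
    )
    return SwallowMetrics(
        duration_s=swallow_duration(track.stationary, track.frame_rate),
        bolus_area_cm2=area,
        bolus_volume_cm3=volume,
        laryngeal_elevation_mm=laryngeal_elevation(track),
        submental_contraction_pct=submental_contraction(track),
    )


def track_from_ground_truth(scene: PhantomScene, frame_rate: Optional[float] = None) -> LandmarkTrack:
    """Landmark track straight from phantom ground truth (the exact-recovery
    reference)."""
    gt = scene.ground_truth
    if frame_rate is None:
        dt = np.diff(scene.frame_times)
        frame_rate = 1.0 / float(dt.mean()) if len(dt) else 1.0
    return LandmarkTrack(
        positions={
            "most_inferior_thyroid": gt["larynx_track"][:, :2],
            "mandible_right_edge": gt["mandible_track"][:, :2],
            "hyoid_left_edge": gt["hyoid_track"][:, :2],
        },
        bolus_masks=gt["bolus_masks"],
        stationary=gt["stationary"],
        frame_rate=frame_rate,
        voxel_size=scene.voxel_size,
    )


# ---------------------------------------------------------------------------
# template-based tracking on reconstructed phantom series (validation aid)
# ---------------------------------------------------------------------------

def _ellipse_template(semi_axes_vox: tuple[float, float], amplitude: float,
                      blur: float = 0.7) -> np.ndarray:
    ry, rx = semi_axes_vox
    hy, hx = int(np.ceil(ry)) + 2, int(np.ceil(rx)) + 2
    y, x = np.mgrid[-hy:hy + 1, -hx:hx + 1]
    t = amplitude * ((y / ry) ** 2 + (x / rx) ** 2 <= 1.0)
    return gaussian_filter(t.astype(float), blur)


def _track_blob(series_mag: np.ndarray, z_slice: int, template: np.ndarray,
                rest_vox: tuple[float, float], window_vox: tuple[int, int, int, int],
                saturate: float, max_step_vox: int = 4) -> np.ndarray:
    """Per-frame (y, x) voxel position of the template's best NCC match.

    The global search window around the rest position bounds the whole
    track; within it, each frame searches only ``max_step_vox`` around the
    previous match (structures move a few mm per frame at most), which keeps
    the tracker from locking onto look-alike structures passing nearby.
    """
    t_frames = series_mag.shape[0]
    out = np.zeros((t_frames, 2))
    hy, hx = template.shape[0] // 2, template.shape[1] // 2
    y0, x0 = rest_vox
    up, down, left, right = window_vox
    gylo, gyhi = int(y0) - up, int(y0) + down
    gxlo, gxhi = int(x0) - left, int(x0) + right
    prev = (int(round(y0)), int(round(x0)))
    for t in range(t_frames):
        ylo = max(max(prev[0] - max_step_vox, gylo) - hy, 0)
        yhi = min(min(prev[0] + max_step_vox, gyhi) + hy + 1, series_mag.shape[2])
        xlo = max(max(prev[1] - max_step_vox, gxlo) - hx, 0)
        xhi = min(min(prev[1] + max_step_vox, gxhi) + hx + 1, series_mag.shape[3])
        img = np.minimum(series_mag[t, z_slice, ylo:yhi, xlo:xhi], saturate)
        score = match_template(img, template, pad_input=False)
        iy, ix = np.unravel_index(np.argmax(score), score.shape)
        prev = (ylo + iy + hy, xlo + ix + hx)
        # parabolic sub-voxel refinement of the correlation peak
        dy = dx = 0.0
        if 0 < iy < score.shape[0] - 1:
            den = score[iy - 1, ix] - 2 * score[iy, ix] + score[iy + 1, ix]
            if den < 0:
                dy = np.clip(0.5 * (score[iy - 1, ix] - score[iy + 1, ix]) / den, -0.5, 0.5)
        if 0 < ix < score.shape[1] - 1:
            den = score[iy, ix - 1] - 2 * score[iy, ix] + score[iy, ix + 1]
            if den < 0:
                dx = np.clip(0.5 * (score[iy, ix - 1] - score[iy, ix + 1]) / den, -0.5, 0.5)
        out[t] = (prev[0] + dy, prev[1] + dx)
    return out


def segment_bolus(series_mag: np.ndarray, threshold: float) -> np.ndarray:
    """Bolus masks per frame: largest connected component above threshold."""
    t_frames = series_mag.shape[0]
    masks = np.zeros(series_mag.shape, dtype=bool)
    for t in range(t_frames):
        above = series_mag[t] > threshold
        if not above.any():
            continue
        lab, n = label(above)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        masks[t] = lab == (1 + int(np.argmax(sizes)))
    return masks


def track_landmarks(
    series_frames: np.ndarray,
    scene: PhantomScene,
    frame_rate: float,
    motion_threshold_mm: float = 2.5,
) -> LandmarkTrack:
    """Annotate a reconstructed phantom series by template matching.

    Uses the phantom's structure geometry (shapes and rest positions — what
    a human rater also knows) but none of its per-frame motion ground truth.
    Bolus masks come from thresholding at the midpoint between the measured
    tissue and bolus levels; motion-state flags from the displacement of the
    tracked structures (and the bolus centroid speed) against the initial
    rest configuration, thresholded at ``motion_threshold_mm``.
    """
    mag = np.abs(np.asarray(series_frames))
    tmpl_info = scene.ground_truth["templates"]
    vy, vx, _ = scene.voxel_size
    nz, ny, nx = scene.grid
    z_mid = nz // 2
    tissue = tmpl_info["tissue_intensity"]
    mag0 = mag - tissue  # baseline-subtract so templates sit on ~zero

    def rest_vox(info):
        y_mm, x_mm = info["rest_yx_mm"]
        return (y_mm / vy + ny // 2, x_mm / vx + nx // 2)

    lar = tmpl_info["larynx"]
    lar_t = _ellipse_template((lar["semi_axes_mm"][0] / vy, lar["semi_axes_mm"][1] / vx),
                              lar["intensity"] - tissue)
    sat = lar["intensity"] - tissue + 0.05
    elev_up = int(np.ceil(1.6 * 20.0 / vy))  # generous superior search range
    lar_pos = _track_blob(mag0, z_mid, lar_t, rest_vox(lar),
                          (elev_up, 3, 4, 4), sat)
    # most inferior thyroid point = blob centre + inferior semi-axis
    lar_mm = np.stack([(lar_pos[:, 0] - ny // 2) * vy + lar["semi_axes_mm"][0],
                       (lar_pos[:, 1] - nx // 2) * vx], axis=1)

    tracks_mm = {"most_inferior_thyroid": lar_mm}
    # the mandible is rigid (tight window); the hyoid excursion points
    # antero-superiorly, so its window is asymmetric to keep the posterior
    # bolus path out of view
    windows = {"mandible": (3, 3, 3, 3), "hyoid": (4, 2, 4, 2)}
    for name, key in (("mandible_right_edge", "mandible"), ("hyoid_left_edge", "hyoid")):
        info = tmpl_info[key]
        r_vox = (info["radius_mm"] / vy, info["radius_mm"] / vx)
        tmpl = _ellipse_template(r_vox, info["intensity"] - tissue)
        sat_b = info["intensity"] - tissue + 0.05
        pos = _track_blob(mag0, z_mid, tmpl, rest_vox(info), windows[key], sat_b,
                          max_step_vox=3)
        tracks_mm[name] = np.stack([(pos[:, 0] - ny // 2) * vy,
                                    (pos[:, 1] - nx // 2) * vx], axis=1)

    # 3-frame median filter: annotation jitter is frame-isolated, real
    # excursions span many frames
    for name in tracks_mm:
        tracks_mm[name] = median_filter(tracks_mm[name], size=(3, 1), mode="nearest")

    # bolus threshold: midpoint of the measured tissue and bolus levels on
    # the first (rest) frame, robust to the amplitude bias of regularised
    # reconstructions
    m0 = mag[0]
    nonbg = m0 > 0.15 * m0.max()
    tissue_level = float(np.median(m0[nonbg]))
    bolus_level = float(np.percentile(m0[nonbg], 98.5))
    masks = segment_bolus(mag, 0.5 * (tissue_level + bolus_level))

    # motion state: any tracked structure displaced from the initial rest
    # configuration, or the bolus centroid moving between frames
    t_frames = mag.shape[0]
    n_rest = max(2, min(4, t_frames // 6))
    moving = np.zeros(t_frames, dtype=bool)
    for pos in tracks_mm.values():
        rest = np.median(pos[:n_rest], axis=0)
        moving |= np.linalg.norm(pos - rest, axis=1) > motion_threshold_mm
    cents = np.full((t_frames, 2), np.nan)
    vy_, vx_, _ = scene.voxel_size
    for t in range(t_frames):
        if masks[t].any():
            iy, ix = np.nonzero(masks[t].any(axis=0))
            cents[t] = ((iy.mean() - ny // 2) * vy_, (ix.mean() - nx // 2) * vx_)
    speed = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    fast = np.concatenate([[False], speed > motion_threshold_mm])
    moving |= fast | np.concatenate([fast[1:], [False]])
    # despeckle: drop isolated moving frames, bridge isolated stationary gaps
    moving = binary_closing(binary_opening(moving, np.ones(2)), np.ones(3))
    return LandmarkTrack(
        positions=tracks_mm,
        bolus_masks=masks,
        stationary=~moving,
        frame_rate=frame_rate,
        voxel_size=scene.voxel_size,
    )
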