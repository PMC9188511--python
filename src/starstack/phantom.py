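"""Digital phantoms: a textured static object, a dynamic swallowing scene,
and smooth complex coil sensitivities with a coupled noise covariance.

The dynamic phantom is a midsagittal-oriented slab (slices sagittal, the
central slice midsagittal) containing the structures the swallowing metrics
are measured on: a hyperintense bolus that traverses an oral → pharyngeal →
oesophageal path, a larynx body that elevates superiorly, and a
mandible/hyoid landmark pair whose distance (the submental muscle length)
shortens during the swallow.  Intensities are tissue-class constants with
the bolus brightest; no relaxation physics is simulated.  All programmed
motion amplitudes are recorded exactly in the ground truth, so the metrics
module can be validated by round-trip recovery.

In-plane axes: y (axis -2) runs superior -> inferior with increasing index,
x (axis -1) anterior -> posterior.  Positions in ground-truth tracks are in
mm relative to the volume centre, ordered (y_mm, x_mm, z_mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomScene",
    "SensitivityMaps",
    "static_phantom",
    "dynamic_swallow_phantom",
    "coil_sensitivities",
]

# tissue-class intensities; the bolus ("pineapple juice") is the brightest
INTENSITY = {
    "soft_tissue": 0.45,
    "spine": 0.30,
    "mandible": 0.90,
    "hyoid": 0.70,
    "larynx": 0.80,
    "bolus": 1.0,
}


@dataclass
class PhantomScene:
    """Time-resolved complex object plus exhaustive ground truth."""

    frames: np.ndarray  # complex (t, nz, ny, nx)
    frame_times: np.ndarray  # seconds
    voxel_size: tuple[float, float, float]  # mm (y, x, z)
    n_slices: int  # prescribed (non-oversampled) slices
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]


@dataclass
class SensitivityMaps:
    maps: np.ndarray  # complex (coil, nz, ny, nx)
    noise_covariance: np.ndarray  # (coil, coil) Hermitian positive definite

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


def _mm_grid(grid, voxel_size):
    nz, ny, nx = grid
    vy, vx, vz = voxel_size
    y = (np.arange(ny) - ny // 2) * vy
    x = (np.arange(nx) - nx // 2) * vx
    z = (np.arange(nz) - nz // 2) * vz
    return np.meshgrid(z, y, x, indexing="ij")  # (Z, Y, X) each (nz,ny,nx)


def _slab_mask(grid, n_slices):
    """Zero out the slice-oversampling margin so the slab holds the object."""
    nz = grid[0]
    m = np.zeros(grid, dtype=bool)
    lo = (nz - n_slices) // 2
    m[lo:lo + n_slices] = True
    return m


def static_phantom(
    matrix: int = 128,
    n_kz: int = 9,
    n_slices: Optional[int] = None,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 6.0),
    texture_seed: int = 0,
) -> PhantomScene:
    """Single-frame textured phantom (the pineapple stand-in).

    An ellipsoidal body filled with radial wedges plus smoothed speckle, so
    that blurring measurably degrades structural similarity.  Deterministic
    given ``texture_seed``; background voxels are exactly zero.
    """
    if matrix < 32:
        raise ValueError("matrix must be >= 32")
    n_slices = n_slices or n_kz
    rng = np.random.default_rng(texture_seed)
    grid = (n_kz, matrix, matrix)
    Z, Y, X = _mm_grid(grid, voxel_size)
    vy, vx, vz = voxel_size
    ry, rx = 0.38 * matrix * vy, 0.38 * matrix * vx
    rz = 0.45 * n_slices * vz
    body = (Y / ry) ** 2 + (X / rx) ** 2 + (Z / rz) ** 2 <= 1.0
    body &= _slab_mask(grid, n_slices)

    theta = np.arctan2(X, Y)
    wedges = 0.30 * np.cos(8 * theta)
    rad = np.sqrt((Y / ry) ** 2 + (X / rx) ** 2)
    rings = 0.15 * np.cos(2 * np.pi * 3 * rad)
    speckle = gaussian_filter(rng.standard_normal(grid), sigma=(0.5, 1.2, 1.2))
    speckle *= 0.25 / max(speckle.std(), 1e-12)
    img = np.where(body, 0.6 * (1.0 + wedges + rings) + speckle, 0.0)
    img = np.clip(img, 0.0, None) * body
    # soften edges (radial sampling covers the inscribed k-space disc only;
    # a near-bandlimited object keeps the reference reconstruction faithful)
    img = gaussian_filter(img, sigma=(0.0, 0.9, 0.9)) * body

    scene = PhantomScene(
        frames=img[None].astype(complex),
        frame_times=np.array([0.0]),
        voxel_size=voxel_size,
        n_slices=n_slices,
        ground_truth={"body_mask": body, "texture_seed": texture_seed},
    )
    return scene


def _swallow_envelope(times: np.ndarray, onset: float, offset: float) -> np.ndarray:
    """Raised-cosine motion envelope, 0 at rest, normalised to peak 1 over the
    sampled frames so programmed amplitudes are hit exactly."""
    g = np.zeros_like(times)
    inside = (times > onset) & (times < offset)
    phase = (times[inside] - onset) / (offset - onset)
    g[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    if g.max() > 0:
        g = g / g.max()
    return g  # exactly zero outside (onset, offset): rest frames are static


def dynamic_swallow_phantom(
    bolus_volume_ml: float = 20.0,
    laryngeal_elevation_mm: float = 20.0,
    submental_contraction_pct: float = -25.0,
    duration_s: float = 5.0,
    fps: float = 12.4,
    matrix: int = 128,
    n_slices: int = 7,
    n_kz: Optional[int] = None,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 6.0),
    seed: int = 0,
) -> PhantomScene:
    """Dynamic swallowing phantom with exactly-known ground truth.

    Defaults emulate the study conditions: a 20 mL bolus, ~20 mm laryngeal
    elevation and ~-25 % submental shortening over a single swallow in a
    128x128, 7-slice, 2x2x6 mm sagittal slab.
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration_s must be > 0")
    n_kz = n_kz or int(round(1.28 * n_slices))
    grid = (n_kz, matrix, matrix)
    vy, vx, vz = voxel_size
    fov_y = matrix * vy

    n_frames = max(int(round(duration_s * fps)), 2)
    times = np.arange(n_frames) / fps
    onset_t, offset_t = 0.25 * duration_s, 0.75 * duration_s
    g = _swallow_envelope(times, onset_t, offset_t)
    moving = g > 0

    Z, Y, X = _mm_grid(grid, voxel_size)
    slab = _slab_mask(grid, n_slices)

    # static anatomy (fractions of the in-plane FOV, y measured from centre)
    def fy(f):  # fraction of FOV (0 = superior edge) -> mm from centre
        return (f - 0.5) * fov_y

    def fx(f):
        return (f - 0.5) * matrix * vx

    head = (Y / (0.46 * fov_y)) ** 2 + (X / (0.44 * matrix * vx)) ** 2 \
        + (Z / (0.48 * n_slices * vz)) ** 2 <= 1.0
    head &= slab
    spine = (np.abs(X - fx(0.88)) <= 3 * vx) & (np.abs(Y) <= 0.45 * fov_y) & slab

    rng = np.random.default_rng(seed)
    texture = gaussian_filter(rng.standard_normal(grid), sigma=(0.5, 1.5, 1.5))
    texture *= 0.05 / max(texture.std(), 1e-12)

    # larynx: ellipsoid translating superiorly (towards smaller y) by
    # g(t)*elevation.  The layout keeps the bolus path clear of the larynx
    # search region so both remain individually trackable on reconstructions.
    lar_rest = np.array([fy(0.734), fx(0.383)])  # (y_mm, x_mm), central slice
    lar_r = np.array([9.0, 7.0, 6.0])  # mm semi-axes (y, x, z)
    if lar_rest[0] - laryngeal_elevation_mm - lar_r[0] < -0.5 * fov_y:
        raise ValueError("requested laryngeal elevation exceeds the field of view")

    # submental landmark pair: fixed mandible, hyoid moving towards it
    mand = np.array([fy(0.313), fx(0.156)])
    hyoid_rest = np.array([fy(0.453), fx(0.313)])
    rest_vec = hyoid_rest - mand
    rest_len = float(np.linalg.norm(rest_vec))

    # bolus path waypoints (y_mm, x_mm): oral -> pharyngeal -> oesophageal;
    # spaced so the 20 mL bolus ball never enters a landmark search region
    path = np.array([[fy(0.172), fx(0.313)], [fy(0.461), fx(0.578)], [fy(0.852), fx(0.672)]])

    voxel_ml = vy * vx * vz / 1000.0
    k_bolus = int(round(bolus_volume_ml / voxel_ml))

    frames = np.zeros((n_frames,) + grid)
    masks = np.zeros((n_frames,) + grid, dtype=bool)
    larynx_track = np.zeros((n_frames, 3))
    hyoid_track = np.zeros((n_frames, 3))
    mand_track = np.zeros((n_frames, 3))
    sub_len = np.zeros(n_frames)

    # progress along the bolus path follows the integral of the motion
    # envelope so the bolus moves only while the swallow is active
    cum = np.cumsum(g)
    progress = cum / cum[-1] if cum[-1] > 0 else np.zeros_like(cum)

    for t in range(n_frames):
        img = np.zeros(grid)
        img[head] = INTENSITY["soft_tissue"]
        img[spine] = INTENSITY["spine"]

        lar_c = lar_rest + np.array([-laryngeal_elevation_mm, 0.0]) * g[t]
        lar = ((Y - lar_c[0]) / lar_r[0]) ** 2 + ((X - lar_c[1]) / lar_r[1]) ** 2 \
            + (Z / lar_r[2]) ** 2 <= 1.0
        lar &= slab
        # most inferior point of the larynx body (thyroid surrogate)
        larynx_track[t] = [lar_c[0] + lar_r[0], lar_c[1], 0.0]

        hy_c = mand + rest_vec * (1.0 + submental_contraction_pct / 100.0 * g[t])
        blobs = {}
        for c, r, name in ((mand, 6.0, "mandible"), (hy_c, 5.0, "hyoid")):
            blobs[name] = (((Y - c[0]) / r) ** 2 + ((X - c[1]) / r) ** 2
                           + (Z / (1.5 * r)) ** 2 <= 1.0) & slab
        hyoid_track[t] = [hy_c[0], hy_c[1], 0.0]
        mand_track[t] = [mand[0], mand[1], 0.0]
        sub_len[t] = float(np.linalg.norm(hy_c - mand))

        # bolus: exactly k_bolus nearest voxels (mm metric) around the path
        # point; rigid structures displace the fluid and are painted on top
        s = progress[t] * (len(path) - 1)
        i0 = min(int(s), len(path) - 2)
        b_c = path[i0] + (s - i0) * (path[i0 + 1] - path[i0])
        d2 = ((Y - b_c[0]) ** 2 + (X - b_c[1]) ** 2 + Z**2)
        excluded = ~slab | lar | blobs["mandible"] | blobs["hyoid"]
        d2 = np.where(excluded, np.inf, d2)
        flat = np.argpartition(d2.ravel(), k_bolus)[:k_bolus]
        mask = np.zeros(grid, dtype=bool)
        mask.ravel()[flat] = True
        masks[t] = mask
        img[mask] = INTENSITY["bolus"]
        img[lar] = INTENSITY["larynx"]
        img[blobs["mandible"]] = INTENSITY["mandible"]
        img[blobs["hyoid"]] = INTENSITY["hyoid"]

        img = np.clip(img + texture * (img > 0), 0.0, None)
        frames[t] = img

    onset_idx = int(np.argmax(moving)) if moving.any() else 0
    offset_idx = int(n_frames - np.argmax(moving[::-1])) if moving.any() else 0

    gt = {
        "bolus_masks": masks,
        "bolus_volume_ml": k_bolus * voxel_ml,
        "larynx_track": larynx_track,
        "hyoid_track": hyoid_track,
        "mandible_track": mand_track,
        "submental_length_mm": sub_len,
        "stationary": ~moving,
        "swallow_onset": onset_idx,
        "swallow_offset": offset_idx,
        "programmed": {
            "bolus_volume_ml": bolus_volume_ml,
            "laryngeal_elevation_mm": laryngeal_elevation_mm,
            "submental_contraction_pct": submental_contraction_pct,
        },
        "envelope": g,
        "seed": seed,
        # geometry needed by template-based landmark tracking on recons
        "templates": {
            "larynx": {"semi_axes_mm": lar_r.tolist(), "rest_yx_mm": lar_rest.tolist(),
                       "intensity": INTENSITY["larynx"]},
            "mandible": {"radius_mm": 6.0, "rest_yx_mm": mand.tolist(),
                         "intensity": INTENSITY["mandible"]},
            "hyoid": {"radius_mm": 5.0, "rest_yx_mm": hyoid_rest.tolist(),
                      "intensity": INTENSITY["hyoid"]},
            "tissue_intensity": INTENSITY["soft_tissue"],
            "bolus_intensity": INTENSITY["bolus"],
        },
    }
    return PhantomScene(
        frames=frames.astype(complex),
        frame_times=times,
        voxel_size=voxel_size,
        n_slices=n_slices,
        ground_truth=gt,
    )


def coil_sensitivities(
    n_coils: int,
    grid: tuple[int, int, int],
    smoothness: float = 0.8,
    seed: int = 0,
) -> SensitivityMaps:
    """Smooth complex coil maps around the object plus a coupled noise covariance.

    Each coil is a broad Gaussian lobe centred on a ring around the FOV with a
    low-order spatial phase; a constant floor keeps the root-sum-of-squares
    bounded away from zero everywhere.  ``smoothness`` scales the lobe width in
    FOV units; ``smoothness=inf`` yields perfectly flat unit maps (the
    identity-coil limit, in which SENSE reduces to gridding).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nz, ny, nx = grid
    rng = np.random.default_rng(seed)
    maps = np.empty((n_coils,) + tuple(grid), dtype=complex)
    zz, yy, xx = np.meshgrid(
        np.linspace(-0.5, 0.5, nz), np.linspace(-0.5, 0.5, ny),
        np.linspace(-0.5, 0.5, nx), indexing="ij",
    )
    if np.isinf(smoothness):
        maps[:] = 1.0
    else:
        sigma = 0.6 * smoothness
        for c in range(n_coils):
            ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
            cy, cx = 0.55 * np.sin(ang), 0.55 * np.cos(ang)
            cz = rng.uniform(-0.3, 0.3)
            mag = 0.15 + np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2 + (zz - cz) ** 2))
                                / (2 * sigma**2))
            a, b, cph, d = rng.normal(0, 1.0 / smoothness, 4)
            phase = a + b * yy + cph * xx + d * zz
            maps[c] = mag * np.exp(1j * phase)

    a = (rng.standard_normal((n_coils, n_coils)) + 1j * rng.standard_normal((n_coils, n_coils)))
    cov = a @ a.conj().T / n_coils + 0.5 * np.eye(n_coils)
    cov = 0.5 * (cov + cov.conj().T)
    return SensitivityMaps(maps=maps, noise_covariance=cov)
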