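"""Multi-coil radial k-space simulation of a phantom scene along a schedule.

The forward model per acquisition event is the non-uniform Fourier transform
of (object state x coil sensitivity) sampled on that event's spoke, where the
object state is the phantom frame nearest in time (no intra-spoke motion).
Optional hardware imperfections:

* complex Gaussian noise with a specified coil covariance (scaled by
  ``noise_sd``),
* a global gradient delay that shifts every spoke's samples along its own
  readout by a (fractional) number of samples,
* a heuristic first-order eddy-current model, off by default, with two
  terms that grow with the azimuthal jump from the previous event: a
  constant phase per event (``eddy_coupling``, rad/deg) and a k-space
  trajectory offset along the *gradient-change* direction
  (``eddy_shift_coupling``, cycles/FOV per unit change of the readout
  direction vector, i.e. |dk| = coupling * 2 sin(dAz/2)).  The phase term
  follows the azimuth increment literally but is a constant — hence a
  harmless global phase — for constant-increment (continuously rotated)
  patterns.  The offset term models the residual gradient left by a large
  gradient step: its component perpendicular to the readout is mutually
  inconsistent between opposed spokes, which is what actually degrades
  large-jump patterns in the image domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nufft import SosNufft
from .phantom import PhantomScene, SensitivityMaps
from .trajectory import (
    Pattern,
    SequenceParams,
    SpokeSchedule,
    TrajectoryConfig,
    build_schedule,
    nyquist_spokes_per_slice,
    spoke_coordinates,
)

__all__ = ["KSpaceData", "simulate_kspace", "acquire_fully_sampled",
           "eddy_phase_errors", "readout_shift"]


@dataclass
class KSpaceData:
    """Complex radial samples with coordinates and acquisition metadata."""

    samples: np.ndarray  # complex (event, readout, coil)
    coords: np.ndarray  # (event, readout, 3) in cycles/FOV, (kz, ky, kx)
    schedule: SpokeSchedule
    noise_covariance: Optional[np.ndarray]  # (coil, coil) or None
    sequence: SequenceParams
    metadata: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.samples.shape[-1]

    def validate(self) -> None:
        if self.samples.shape[0] != len(self.schedule):
            raise ValueError("event count does not match schedule")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")
        nyq = self.sequence.matrix / 2
        if np.abs(self.coords[..., 1:]).max() > nyq + 1e-9:
            raise ValueError("in-plane coordinates beyond the Nyquist extent")


def eddy_phase_errors(schedule: SpokeSchedule, eddy_coupling: float) -> np.ndarray:
    """Per-event phase error (radians): coupling x wrapped azimuth increment.

    The increment is the signed angular jump from the previous event wrapped
    to (-180, 180] degrees; the first event has no predecessor and no error.
    """
    daz = np.diff(schedule.azimuth)
    daz = (daz + 180.0) % 360.0 - 180.0
    return np.concatenate([[0.0], eddy_coupling * daz])


def readout_shift(samples: np.ndarray, shift: float) -> np.ndarray:
    """Circularly shift samples along the readout axis (axis 1) by a
    fractional number of samples: out[i] = in[i - shift]."""
    n = samples.shape[1]
    q = np.fft.fftfreq(n, d=1.0 / n)  # integer frequencies
    phase = np.exp(-2j * np.pi * q * shift / n)
    return np.fft.ifft(np.fft.fft(samples, axis=1) * phase[None, :, None], axis=1)


def simulate_kspace(
    scene: PhantomScene,
    schedule: SpokeSchedule,
    maps: SensitivityMaps,
    noise_sd: float = 0.0,
    gradient_delay_samples: float = 0.0,
    eddy_coupling: float = 0.0,
    eddy_shift_coupling: float = 0.0,
    seed: Optional[int] = None,
    width: int = 8,
) -> KSpaceData:
    """Simulate the multi-coil acquisition of ``scene`` along ``schedule``."""
    params = schedule.sequence
    grid = scene.grid
    if maps.maps.shape[1:] != grid:
        raise ValueError(
            f"coil map grid {maps.maps.shape[1:]} does not match scene grid {grid}")
    if grid[0] != schedule.n_kz or grid[1] != params.matrix:
        raise ValueError("scene grid does not match schedule geometry")

    coords = spoke_coordinates(schedule, params)
    n_events, n_read = coords.shape[:2]
    n_coils = maps.n_coils
    samples = np.zeros((n_events, n_read, n_coils), dtype=complex)

    # trajectory error: data acquired at offset k-locations but indexed at
    # the nominal ones (the reconstruction never sees the true trajectory)
    sim_coords = coords
    if eddy_shift_coupling != 0.0:
        az = np.deg2rad(schedule.azimuth)
        e = np.stack([np.sin(az), np.cos(az)], axis=1)  # (ky, kx) direction
        dk = np.zeros_like(e)
        dk[1:] = eddy_shift_coupling * np.diff(e, axis=0)
        sim_coords = coords.copy()
        sim_coords[..., 1:] += dk[:, None, :]

    # nearest phantom frame per event
    frame_of = np.abs(scene.frame_times[None, :] - schedule.time[:, None]).argmin(axis=1)
    for f in np.unique(frame_of):
        ev = np.nonzero(frame_of == f)[0]
        op = SosNufft(sim_coords[ev], schedule.kz_index[ev], schedule.n_kz,
                      (params.matrix, params.matrix), width=width)
        weighted = maps.maps * scene.frames[f][None]  # (coil, nz, ny, nx)
        s = op.forward(weighted)  # (coil, n_ev, n_read)
        samples[ev] = np.moveaxis(s, 0, -1)

    if eddy_coupling != 0.0:
        phase = eddy_phase_errors(schedule, eddy_coupling)
        samples = samples * np.exp(1j * phase)[:, None, None]
    if gradient_delay_samples != 0.0:
        samples = readout_shift(samples, gradient_delay_samples)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        chol = np.linalg.cholesky(maps.noise_covariance)
        eps = (rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)) \
            / np.sqrt(2.0)
        samples = samples + noise_sd * (eps @ chol.T)

    data = KSpaceData(
        samples=samples,
        coords=coords,
        schedule=schedule,
        noise_covariance=maps.noise_covariance,
        sequence=params,
        metadata={
            "noise_sd": noise_sd,
            "gradient_delay_samples": gradient_delay_samples,
            "eddy_coupling": eddy_coupling,
            "eddy_shift_coupling": eddy_shift_coupling,
            "seed": seed,
        },
    )
    data.validate()
    return data


def acquire_fully_sampled(
    scene: PhantomScene,
    pattern: Pattern | str,
    params: SequenceParams,
    maps: SensitivityMaps,
    spokes_per_slice: Optional[int] = None,
    tiny_angle_order: Optional[int] = None,
    **sim_kwargs,
) -> KSpaceData:
    """Fully sampled acquisition of a static scene (the SSIM reference data).

    The default spoke count is the radial Nyquist rule round(pi*n_readout/2),
    i.e. 402 spokes per slice for 256 readout samples.
    """
    if scene.n_frames != 1:
        raise ValueError("acquire_fully_sampled expects a static (single-frame) scene")
    nsp = spokes_per_slice or nyquist_spokes_per_slice(params.n_readout)
    config = TrajectoryConfig(pattern=Pattern(pattern), spokes_per_slice=nsp,
                              tiny_angle_order=tiny_angle_order, sequence=params)
    schedule = build_schedule(config)
    return simulate_kspace(scene, schedule, maps, **sim_kwargs)
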