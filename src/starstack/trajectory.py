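"""Golden-angle and tiny-golden-angle stack-of-stars trajectory design.

A stack-of-stars (SOS) acquisition samples 3D k-space with radial spokes in
the kx–ky plane and Cartesian phase encoding along kz.  One *star* is a full
set of kz encodings acquired before the in-plane azimuth advances (or, for
rotated patterns, while it advances).  This module generates the ordered
acquisition schedule for the patterns compared in the simulation study:

* ``RADIAL2D``   – single-plane golden-angle radial (the 2D baseline),
* ``ASOS``       – aligned SOS: every kz encoding of a star shares one azimuth,
* ``RSOS_GR``    – rotated SOS with a golden-ratio kz-plane offset (comparator),
* ``RSOS_PSI1``  – continuously rotated SOS, golden-angle increment per event,
* ``RSOS_PSI9``  – continuously rotated SOS, tiny-golden-angle increment.

Angles are stored in degrees modulo 360; spokes are full diameters, so
opposed spokes are distinct events (required for gradient-delay estimation).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


class Pattern(str, enum.Enum):
    """Supported sampling patterns."""

    RADIAL2D = "RADIAL2D"
    ASOS = "ASOS"
    RSOS_GR = "RSOS_GR"
    RSOS_PSI1 = "RSOS_PSI1"
    RSOS_PSI9 = "RSOS_PSI9"


def tiny_golden_angle(order: int) -> float:
    """Tiny golden angle psi_N = 180 / (phi + N - 1) in degrees.

    ``order=1`` gives the classical golden angle (~111.25 deg); larger orders
    give smaller increments that retain near-uniform azimuthal coverage while
    reducing the eddy currents induced by large gradient jumps.
    """
    if not isinstance(order, (int, np.integer)) or isinstance(order, bool):
        raise TypeError(f"order must be a positive integer, got {order!r}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    return 180.0 / (GOLDEN_RATIO + order - 1)


GOLDEN_ANGLE_DEG = tiny_golden_angle(1)


@dataclass(frozen=True)
class SequenceParams:
    """Pulse-sequence timing and geometry (TE/flip angle are metadata only)."""

    tr: float = 3.0e-3  # seconds per readout event
    te: float = 1.26e-3
    flip_angle: float = 10.0  # degrees
    n_readout: int = 256
    matrix: int = 128
    n_slices: int = 7
    oversampling_factor: float = 1.28
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 6.0)  # mm (y, x, z in-plane pair + slice)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_readout < 2:
            raise ValueError("n_readout must be >= 2")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.oversampling_factor < 1:
            raise ValueError("oversampling_factor must be >= 1")

    @property
    def n_kz(self) -> int:
        """Number of kz encodings including slice oversampling (rounded)."""
        return int(round(self.oversampling_factor * self.n_slices))


@dataclass(frozen=True)
class TrajectoryConfig:
    pattern: Pattern
    spokes_per_slice: int = 402
    tiny_angle_order: Optional[int] = None  # default: n_kz for RSOS_PSI9
    sequence: SequenceParams = field(default_factory=SequenceParams)

    def __post_init__(self) -> None:
        if self.spokes_per_slice < 1:
            raise ValueError("spokes_per_slice must be >= 1")
        object.__setattr__(self, "pattern", Pattern(self.pattern))

    def resolved_tiny_order(self) -> int:
        if self.tiny_angle_order is not None:
            return int(self.tiny_angle_order)
        if self.pattern is Pattern.RSOS_PSI9:
            # the tiny-golden-angle number is tied to the kz count so that one
            # star accumulates close to one full azimuthal "step"
            return self.sequence.n_kz
        return 1


@dataclass(frozen=True)
class SpokeSchedule:
    """Ordered acquisition events of a stack-of-stars scan.

    Columns (parallel arrays): ``global_index`` (0..N-1, step 1),
    ``star_index``, ``kz_index`` in [0, n_kz), ``azimuth`` in degrees
    [0, 360), ``time`` = global_index * TR in seconds.
    """

    pattern: Pattern
    global_index: np.ndarray
    star_index: np.ndarray
    kz_index: np.ndarray
    azimuth: np.ndarray
    time: np.ndarray
    n_kz: int
    sequence: SequenceParams

    def __len__(self) -> int:
        return len(self.global_index)

    @property
    def spokes_per_slice(self) -> int:
        return len(self) // self.n_kz

    def validate(self) -> None:
        gi = self.global_index
        if not np.array_equal(gi, np.arange(len(gi))):
            raise ValueError("global_index must increase by 1 from 0")
        if np.any((self.kz_index < 0) | (self.kz_index >= self.n_kz)):
            raise ValueError("kz_index out of range")
        if np.any(self.time < 0) or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be non-negative and strictly increasing")
        for s in np.unique(self.star_index):
            kz = np.sort(self.kz_index[self.star_index == s])
            if not np.array_equal(kz, np.arange(self.n_kz)):
                raise ValueError(f"star {s} does not visit every kz exactly once")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "global_index": self.global_index,
                "star_index": self.star_index,
                "kz_index": self.kz_index,
                "azimuth_deg": self.azimuth,
                "time_s": self.time,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sequence: SequenceParams, pattern: Pattern = Pattern.ASOS,
                 n_kz: Optional[int] = None) -> "SpokeSchedule":
        df = pd.read_csv(path)
        n_kz = int(n_kz if n_kz is not None else df["kz_index"].max() + 1)
        return cls(
            pattern=Pattern(pattern),
            global_index=df["global_index"].to_numpy(int),
            star_index=df["star_index"].to_numpy(int),
            kz_index=df["kz_index"].to_numpy(int),
            azimuth=df["azimuth_deg"].to_numpy(float),
            time=df["time_s"].to_numpy(float),
            n_kz=n_kz,
            sequence=sequence,
        )


@dataclass(frozen=True)
class FrameBinning:
    """Contiguous, non-overlapping grouping of events into temporal frames."""

    frame_assignments: np.ndarray  # event index -> frame index, -1 for dropped
    events_per_frame: int
    frame_duration: float  # seconds
    frame_rate: float  # fps
    n_frames: int
    event_offset: int = 0  # first event of frame 0 (sliding-window shift)

    def events_of(self, frame: int) -> np.ndarray:
        return np.nonzero(self.frame_assignments == frame)[0]


def build_schedule(config: TrajectoryConfig) -> SpokeSchedule:
    """Generate the ordered acquisition schedule for the configured pattern.

    The kz direction is the inner scan loop (fully sampled per star, linear
    ascending), the in-plane azimuth the outer loop.  For the continuously
    rotated patterns the azimuthal increment over kz is continued by the
    in-plane increment, i.e. the azimuth is a single arithmetic progression
    over the *global* event index.
    """
    seq = config.sequence
    pattern = config.pattern
    n_kz = 1 if pattern is Pattern.RADIAL2D else seq.n_kz
    n_spokes = config.spokes_per_slice
    n_events = n_spokes * n_kz

    g = np.arange(n_events)
    star = g // n_kz
    kz = g % n_kz  # linear ascending within each star

    if pattern is Pattern.RADIAL2D:
        azimuth = (g * GOLDEN_ANGLE_DEG) % 360.0
    elif pattern is Pattern.ASOS:
        azimuth = (star * GOLDEN_ANGLE_DEG) % 360.0
    elif pattern is Pattern.RSOS_PSI1:
        azimuth = (g * GOLDEN_ANGLE_DEG) % 360.0
    elif pattern is Pattern.RSOS_PSI9:
        psi = tiny_golden_angle(config.resolved_tiny_order())
        azimuth = (g * psi) % 360.0
    elif pattern is Pattern.RSOS_GR:
        # Comparator with a documented convention: uniform azimuth spacing
        # 180/n_spokes within each kz partition, partitions offset from each
        # other by kz_index * (golden angle / n_kz).  Approximate stand-in for
        # the number-of-spokes-dependent scheme it emulates; incompatible with
        # a sliding window by construction.
        azimuth = (star * (180.0 / n_spokes) + kz * (GOLDEN_ANGLE_DEG / n_kz)) % 360.0
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {pattern}")

    sched = SpokeSchedule(
        pattern=pattern,
        global_index=g,
        star_index=star,
        kz_index=kz,
        azimuth=azimuth.astype(float),
        time=g * seq.tr,
        n_kz=n_kz,
        sequence=seq,
    )
    sched.validate()
    return sched


def spoke_coordinates(schedule: SpokeSchedule, params: Optional[SequenceParams] = None) -> np.ndarray:
    """K-space sample coordinates, shape (n_events, n_readout, 3) = (kz, ky, kx).

    Units are cycles/FOV: the Cartesian grid of a ``matrix``-sized image maps
    to integer coordinates.  Each spoke is a full diameter through the
    in-plane origin; the readout is oversampled (n_readout >= matrix) with
    spacing matrix/n_readout, so sample ``n_readout//2`` sits exactly at
    in-plane k=0.  kz partitions are integers centred on 0.
    """
    params = params or schedule.sequence
    n_read = params.n_readout
    kr = (np.arange(n_read) - n_read // 2) * (params.matrix / n_read)
    az = np.deg2rad(schedule.azimuth)
    kx = np.cos(az)[:, None] * kr[None, :]
    ky = np.sin(az)[:, None] * kr[None, :]
    kz = (schedule.kz_index - schedule.n_kz // 2).astype(float)
    kz = np.broadcast_to(kz[:, None], kx.shape)
    return np.stack([kz, ky, kx], axis=-1)


def bin_frames(schedule: SpokeSchedule, spokes_per_slice_per_frame: int,
               event_offset: int = 0) -> FrameBinning:
    """Bin consecutive events into frames of a fixed spoke budget per slice.

    Frame duration = spokes_per_slice_per_frame * n_kz * TR; a trailing
    partial frame (and the ``event_offset`` leading events, used by the
    sliding window) are dropped.
    """
    if spokes_per_slice_per_frame < 1:
        raise ValueError("spokes_per_slice_per_frame must be >= 1")
    per_frame = spokes_per_slice_per_frame * schedule.n_kz
    n_events = len(schedule)
    n_frames = (n_events - event_offset) // per_frame
    assign = np.full(n_events, -1, dtype=int)
    idx = np.arange(event_offset, event_offset + n_frames * per_frame)
    assign[idx] = (idx - event_offset) // per_frame
    duration = per_frame * schedule.sequence.tr
    return FrameBinning(
        frame_assignments=assign,
        events_per_frame=per_frame,
        frame_duration=duration,
        frame_rate=1.0 / duration,
        n_frames=n_frames,
        event_offset=event_offset,
    )


def nyquist_spokes_per_slice(n_readout: int) -> int:
    """Fully sampled radial spoke count: round(pi * n_readout / 2).

    With a 2x oversampled readout this is the azimuthal Nyquist criterion for
    full diameters (402 spokes for 256 readout samples).
    """
    return int(round(math.pi * n_readout / 2.0))
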