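"""Container formats: HDF5 k-space, NIfTI image series, YAML run configs.

Conventions stored with every artifact: image arrays ordered (t, z, y, x);
k-space coordinates in cycles/FOV; 0-based indexing; voxel geometry in mm in
the NIfTI header (slice thickness in the z pixdim, frame interval in the
time pixdim) with a JSON sidecar carrying the frame rate and provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .forward_model import KSpaceData
from .recon import ImageSeries, ReconConfig
from .trajectory import Pattern, SequenceParams, SpokeSchedule, TrajectoryConfig

__all__ = [
    "RunConfig",
    "write_kspace", "read_kspace",
    "write_image_series", "read_image_series",
    "load_trajectory_config", "load_recon_config", "config_hash",
]


@dataclasses.dataclass
class RunConfig:
    """A full pipeline run: trajectory + reconstruction + phantom settings,
    seeds and output paths.  Fully YAML-serialisable; its hash is embedded
    in every artifact the pipeline writes."""

    trajectory: TrajectoryConfig
    recon: "ReconConfig"
    phantom: dict
    seed: int = 0
    outputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        traj = raw.get("trajectory", {})
        seq = traj.pop("sequence", {})
        if "voxel_size" in seq:
            seq["voxel_size"] = tuple(seq["voxel_size"])
        return cls(
            trajectory=TrajectoryConfig(sequence=SequenceParams(**seq), **traj),
            recon=ReconConfig(**raw.get("recon", {})),
            phantom=raw.get("phantom", {}),
            seed=int(raw.get("seed", 0)),
            outputs=raw.get("outputs", {}),
        )

    def hash(self) -> str:
        return config_hash(self)

_SCHEDULE_COLUMNS = ("global_index", "star_index", "kz_index", "azimuth", "time")


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serialisable configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_kspace(path, data: KSpaceData) -> None:
    """Persist a KSpaceData container (datasets /samples, /coords,
    /schedule/*, /noise_cov; sequence and run metadata as attributes)."""
    sched = data.schedule
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=data.samples)
        f.create_dataset("coords", data=data.coords)
        g = f.create_group("schedule")
        for col in _SCHEDULE_COLUMNS:
            g.create_dataset(col, data=getattr(sched, col))
        g.attrs["pattern"] = sched.pattern.value
        g.attrs["n_kz"] = sched.n_kz
        if data.noise_covariance is not None:
            f.create_dataset("noise_cov", data=data.noise_covariance)
        seq = dataclasses.asdict(data.sequence)
        f.attrs["sequence"] = json.dumps(seq)
        f.attrs["metadata"] = json.dumps(
            {k: v for k, v in data.metadata.items() if _jsonable(v)}, default=str)
        f.attrs["config_hash"] = config_hash(
            {"sequence": seq, "pattern": sched.pattern.value,
             "metadata_seed": data.metadata.get("seed")})


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        for name in ("samples", "coords", "schedule"):
            if name not in f:
                raise KeyError(f"k-space container is missing dataset '{name}'")
        seq = SequenceParams(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in json.loads(f.attrs["sequence"]).items()})
        g = f["schedule"]
        for col in _SCHEDULE_COLUMNS:
            if col not in g:
                raise KeyError(f"k-space container is missing dataset 'schedule/{col}'")
        sched = SpokeSchedule(
            pattern=Pattern(g.attrs["pattern"]),
            global_index=g["global_index"][()],
            star_index=g["star_index"][()],
            kz_index=g["kz_index"][()],
            azimuth=g["azimuth"][()],
            time=g["time"][()],
            n_kz=int(g.attrs["n_kz"]),
            sequence=seq,
        )
        return KSpaceData(
            samples=f["samples"][()],
            coords=f["coords"][()],
            schedule=sched,
            noise_covariance=f["noise_cov"][()] if "noise_cov" in f else None,
            sequence=seq,
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


def write_image_series(path, series: ImageSeries, sidecar: bool = True) -> None:
    """4D NIfTI (x, y, z, t axis order on disk) with mm/s pixdims and a JSON
    sidecar for frame rate and provenance."""
    mag = np.abs(series.frames)  # (t, z, y, x)
    arr = np.transpose(mag, (3, 2, 1, 0))  # (x, y, z, t)
    vy, vx, vz = series.voxel_size
    affine = np.diag([vx, vy, vz, 1.0])
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    dt = 1.0 / series.frame_rate if series.frame_rate > 0 else 1.0
    img.header.set_zooms((vx, vy, vz, dt))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    if sidecar:
        side = {
            "frame_rate_fps": series.frame_rate,
            "frame_times_s": np.asarray(series.frame_times).tolist(),
            "voxel_size_mm": list(series.voxel_size),
            "provenance": {k: v for k, v in series.provenance.items() if _jsonable(v)},
        }
        Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def read_image_series(path) -> ImageSeries:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    frames = np.transpose(arr, (3, 2, 1, 0))
    zooms = img.header.get_zooms()
    side_path = Path(str(path) + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        rate = side["frame_rate_fps"]
        times = np.asarray(side["frame_times_s"])
        voxel = tuple(side["voxel_size_mm"])
        prov = side.get("provenance", {})
    else:
        dt = zooms[3] if len(zooms) > 3 and zooms[3] > 0 else 1.0
        rate = 1.0 / dt
        times = np.arange(frames.shape[0]) * dt
        voxel = (float(zooms[1]), float(zooms[0]), float(zooms[2]))
        prov = {}
    return ImageSeries(frames=frames, frame_rate=rate, frame_times=times,
                       voxel_size=voxel, provenance=prov)


def load_trajectory_config(path) -> TrajectoryConfig:
    raw = yaml.safe_load(Path(path).read_text())
    seq = raw.pop("sequence", {})
    if "voxel_size" in seq:
        seq["voxel_size"] = tuple(seq["voxel_size"])
    return TrajectoryConfig(sequence=SequenceParams(**seq), **raw)


def load_recon_config(path) -> ReconConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return ReconConfig(**raw)
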