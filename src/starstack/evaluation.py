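"""Reconstruction quality: SSIM against the fully sampled reference.

The protocol mirrors the phantom experiment: acquire one fully sampled
dataset per pattern, reconstruct the reference with CG-SENSE, reconstruct a
real-time series from the same spokes binned at six per slice per frame with
compressed sensing, and compare the central frame's central slice to the
reference by the structural similarity index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .forward_model import acquire_fully_sampled
from .phantom import PhantomScene, coil_sensitivities
from .recon import (
    ReconConfig,
    cs_recon,
    nrmse,
    prewhiten,
    reference_recon,
    whiten_sensitivities,
)
from .trajectory import Pattern, SequenceParams, bin_frames

__all__ = ["QualityReport", "ssim", "compare_patterns", "difference_image"]


@dataclass(frozen=True)
class QualityReport:
    pattern: str
    n_slices: int
    ssim: float
    nrmse: float
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def ssim(reference: np.ndarray, test: np.ndarray,
         data_range: Optional[float] = None,
         gaussian_weights: bool = True,
         win_size: Optional[int] = None,
         use_sample_covariance: bool = True) -> float:
    """Mean structural similarity of two magnitude images.

    Gaussian 1.5-sigma window and the standard constants K1=0.01, K2=0.03 by
    default; ``data_range`` defaults to the reference maximum.
    """
    ref = np.abs(np.asarray(reference, float))
    tst = np.abs(np.asarray(test, float))
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if data_range is None:
        data_range = float(ref.max())
    return float(structural_similarity(
        ref, tst, data_range=data_range, gaussian_weights=gaussian_weights,
        win_size=win_size, use_sample_covariance=use_sample_covariance,
        K1=0.01, K2=0.03,
    ))


def difference_image(reference: np.ndarray, test: np.ndarray,
                     amplification: float = 5.0) -> np.ndarray:
    """Amplified absolute difference for display (window level x amplification)."""
    return amplification * np.abs(np.abs(reference) - np.abs(test))


def save_montage(reference: np.ndarray, test: np.ndarray, path,
                 amplification: float = 5.0) -> None:
    """PNG montage: reference | accelerated | amplified difference columns,
    one row per supplied 2D slice (display utility)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.abs(np.asarray(reference))
    tst = np.abs(np.asarray(test))
    if ref.ndim == 2:
        ref, tst = ref[None], tst[None]
    n_rows = ref.shape[0]
    vmax = float(ref.max())
    fig, axes = plt.subplots(n_rows, 3, figsize=(7.5, 2.5 * n_rows),
                             squeeze=False)
    for r in range(n_rows):
        cols = (ref[r], tst[r], difference_image(ref[r], tst[r], amplification))
        for c, (img, title) in enumerate(zip(
                cols, ("reference", "accelerated", f"difference x{amplification:g}"))):
            ax = axes[r][c]
            ax.imshow(img, cmap="gray", vmin=0, vmax=vmax)
            ax.set_axis_off()
            if r == 0:
                ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_patterns(
    scene: PhantomScene,
    patterns: Sequence[Pattern | str],
    n_slices_list: Sequence[int],
    params: Optional[SequenceParams] = None,
    n_coils: int = 6,
    noise_sd: float = 0.0,
    eddy_coupling: float = 0.0,
    eddy_shift_coupling: float = 0.0,
    tiny_angle_order: Optional[int] = None,
    recon_config: ReconConfig = ReconConfig(),
    reference_iterations: int = 60,
    seed: int = 0,
    scene_factory=None,
) -> list[QualityReport]:
    """SSIM of the central CS frame vs the fully sampled reference per
    (pattern, slice count).

    The scene must be static; if ``scene_factory`` is given it is called as
    ``scene_factory(n_kz, n_slices)`` to rebuild the phantom per slice count.
    Deterministic given the seeds.
    """
    params = params or SequenceParams()
    reports = []
    for n_slices in n_slices_list:
        p = SequenceParams(
            tr=params.tr, te=params.te, flip_angle=params.flip_angle,
            n_readout=params.n_readout, matrix=params.matrix,
            n_slices=n_slices, oversampling_factor=params.oversampling_factor,
            voxel_size=params.voxel_size,
        )
        n_kz = p.n_kz
        sc = scene_factory(n_kz, n_slices) if scene_factory is not None else scene
        if sc.grid[0] != n_kz:
            raise ValueError("scene kz extent does not match the slice count")
        maps = coil_sensitivities(n_coils, sc.grid, seed=seed + 1)
        cfg_payload = {
            "recon": recon_config.__dict__, "noise_sd": noise_sd,
            "eddy_coupling": eddy_coupling,
            "eddy_shift_coupling": eddy_shift_coupling, "n_coils": n_coils,
            "matrix": p.matrix, "n_slices": n_slices, "seed": seed,
        }
        chash = hashlib.sha1(
            json.dumps(cfg_payload, sort_keys=True, default=str).encode()).hexdigest()[:12]
        for pattern in patterns:
            data = acquire_fully_sampled(
                sc, Pattern(pattern), p, maps,
                tiny_angle_order=tiny_angle_order,
                noise_sd=noise_sd, eddy_coupling=eddy_coupling,
                eddy_shift_coupling=eddy_shift_coupling, seed=seed)
            dw = prewhiten(data)
            mw = whiten_sensitivities(maps, dw.metadata["whitening_matrix"])
            ref = reference_recon(dw, mw, max_iterations=reference_iterations)
            binning = bin_frames(dw.schedule, recon_config.spokes_per_slice_per_frame)
            series = cs_recon(dw, binning, mw, recon_config, seed=seed)
            z_mid = n_kz // 2
            ref_sl = np.abs(ref.frames[0, z_mid])
            cs_sl = np.abs(series.frames[binning.n_frames // 2, z_mid])
            reports.append(QualityReport(
                pattern=Pattern(pattern).value,
                n_slices=n_slices,
                ssim=ssim(ref_sl, cs_sl),
                nrmse=nrmse(ref_sl, cs_sl),
                config_hash=chash,
            ))
    return reports
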