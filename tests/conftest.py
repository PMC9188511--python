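"""Shared fixtures and independent oracles.

The direct-DFT oracles here are deliberately naive O(N*M) summations — they
are the reference the fast transforms are checked against and must stay
independent of the gridding implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from starstack import (
    SequenceParams,
    TrajectoryConfig,
    build_schedule,
    coil_sensitivities,
    dynamic_swallow_phantom,
    static_phantom,
)


def dft_forward_3d(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Direct non-uniform DFT: s(k) = sum_u f(u) exp(-2pi i k.(u-u0)/n).

    ``volume`` is (nz, ny, nx); ``coords`` is (..., 3) ordered (kz, ky, kx)
    in cycles/FOV.  Pure summation, no FFT.
    """
    nz, ny, nx = volume.shape
    flat = coords.reshape(-1, 3)
    z = np.arange(nz) - nz // 2
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    phz = np.exp(-2j * np.pi * flat[:, 0, None] * z[None, :] / nz)
    phy = np.exp(-2j * np.pi * flat[:, 1, None] * y[None, :] / ny)
    phx = np.exp(-2j * np.pi * flat[:, 2, None] * x[None, :] / nx)
    out = np.einsum("mz,my,mx,zyx->m", phz, phy, phx, volume.astype(complex))
    return out.reshape(coords.shape[:-1])


def dft_adjoint_3d(samples: np.ndarray, coords: np.ndarray,
                   shape: tuple[int, int, int]) -> np.ndarray:
    """Exact adjoint of `dft_forward_3d`."""
    nz, ny, nx = shape
    flat_s = np.asarray(samples, complex).ravel()
    flat = coords.reshape(-1, 3)
    z = np.arange(nz) - nz // 2
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    phz = np.exp(2j * np.pi * flat[:, 0, None] * z[None, :] / nz)
    phy = np.exp(2j * np.pi * flat[:, 1, None] * y[None, :] / ny)
    phx = np.exp(2j * np.pi * flat[:, 2, None] * x[None, :] / nx)
    return np.einsum("m,mz,my,mx->zyx", flat_s, phz, phy, phx)


@pytest.fixture(scope="session")
def tiny_params() -> SequenceParams:
    """32x32 in-plane, 3 kz encodings — the oracle-equivalence scale."""
    return SequenceParams(matrix=32, n_readout=64, n_slices=3,
                          oversampling_factor=1.0)


@pytest.fixture(scope="session")
def small_params() -> SequenceParams:
    """48x48, 5 slices (6 kz) — the closed-loop reconstruction scale."""
    return SequenceParams(matrix=48, n_readout=96, n_slices=5,
                          oversampling_factor=1.28)


@pytest.fixture(scope="session")
def small_static_scene(small_params):
    return static_phantom(matrix=small_params.matrix, n_kz=small_params.n_kz,
                          n_slices=small_params.n_slices, texture_seed=3)


@pytest.fixture(scope="session")
def small_maps(small_static_scene):
    return coil_sensitivities(5, small_static_scene.grid, seed=4)


@pytest.fixture(scope="session")
def small_full_data(small_static_scene, small_params, small_maps):
    """Noiseless fully sampled acquisition of the static phantom."""
    from starstack import acquire_fully_sampled

    return acquire_fully_sampled(small_static_scene, "RSOS_PSI1",
                                 small_params, small_maps)


@pytest.fixture(scope="session")
def small_whitened(small_full_data, small_maps):
    from starstack import prewhiten, whiten_sensitivities

    dw = prewhiten(small_full_data)
    mw = whiten_sensitivities(small_maps, dw.metadata["whitening_matrix"])
    return dw, mw


@pytest.fixture(scope="session")
def small_reference(small_whitened):
    from starstack import reference_recon

    dw, mw = small_whitened
    return reference_recon(dw, mw, tolerance=1e-8, max_iterations=100)


@pytest.fixture(scope="session")
def dynamic_scene():
    """Study-condition dynamic phantom at the 64-matrix desk scale."""
    return dynamic_swallow_phantom(matrix=64, n_slices=7, duration_s=5.0,
                                   fps=12.35, seed=11)


@pytest.fixture(scope="session")
def dynamic_recon(dynamic_scene):
    """Compressed-sensing reconstruction of a simulated 5 s swallow.

    Shared by the motion-fidelity and metric-recovery tests; ~2-3 minutes.
    """
    import warnings

    from starstack import (
        ReconConfig,
        SequenceParams,
        TrajectoryConfig,
        bin_frames,
        build_schedule,
        coil_sensitivities,
        cs_recon,
        prewhiten,
        simulate_kspace,
        whiten_sensitivities,
    )

    scene = dynamic_scene
    params = SequenceParams(matrix=64, n_readout=128, n_slices=7)
    n_kz = params.n_kz
    spokes = int(round(5.0 / params.tr)) // n_kz
    sched = build_schedule(TrajectoryConfig(pattern="ASOS",
                                            spokes_per_slice=spokes,
                                            sequence=params))
    maps = coil_sensitivities(6, scene.grid, seed=12)
    data = simulate_kspace(scene, sched, maps,
                           noise_sd=0.01 * np.abs(scene.frames).max(), seed=13)
    dw = prewhiten(data)
    mw = whiten_sensitivities(maps, dw.metadata["whitening_matrix"])
    binning = bin_frames(dw.schedule, 6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = cs_recon(dw, binning, mw, ReconConfig(iterations=40), seed=0)
    return series, binning
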