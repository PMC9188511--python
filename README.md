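# starstack

Desk-scale simulation and reconstruction for **3D real-time stack-of-stars
MRI of swallowing**.

Swallowing disorders (dysphagia) are conventionally graded with
videofluoroscopy, which uses ionising radiation and projects the anatomy
to 2D.  Real-time MRI is a radiation-free alternative; extending it to 3D
requires a sampling scheme that is fast, motion-robust and
compatible with a sliding-window reconstruction.  The stack-of-stars (SOS)
trajectory — radial spokes in-plane, Cartesian encoding along kz — meets
these needs, and the open design question is how to rotate the spokes:

* **ASOS** — aligned: every kz encoding of a star shares one azimuth, and
  stars advance by the golden angle ψ₁ = 180°/φ ≈ 111.25°;
* **RSOS-ψ₁** — continuously rotated: the azimuth advances by ψ₁ on every
  readout, so the kz (inner) loop's increment is continued by the in-plane
  (outer) loop;
* **RSOS-ψ₉** — continuously rotated by the tiny golden angle
  ψ_N = 180°/(φ+N−1), with N matched to the kz count
  (ψ₉ ≈ 18.71° for 7 slices with 1.28 slice oversampling) — same
  uniformity, much smaller gradient jumps, hence fewer eddy currents;
* **RSOS-GR** — a golden-ratio-rotated comparator (simulation only; not
  sliding-window capable).

The package implements the whole study chain for these patterns:
trajectory generation, point-spread-function incoherence
(|central peak| / SD of side lobes — higher means noise-like aliasing,
which compressed sensing likes), a dynamic digital swallowing phantom
with exact ground truth, multi-coil radial k-space simulation with noise,
gradient-delay and eddy-current imperfections, compressed-sensing
reconstruction (locally-low-rank in plane, λ = 0.001, plus temporal total
variation, λ = 0.005, solved by FISTA with alternating proximal
operators), a sliding window that doubles 6.2 fps to 12 fps, SSIM-based
pattern comparison, and the quantitative swallowing metrics (duration,
bolus area/volume, laryngeal elevation, submental contraction).

## Worked example

```python
from starstack import (SequenceParams, TrajectoryConfig, build_schedule,
                       bin_frames, tiny_golden_angle,
                       nyquist_spokes_per_slice, sweep_incoherence,
                       dynamic_swallow_phantom, track_from_ground_truth,
                       compute_metrics)

print(f"psi_1 = {tiny_golden_angle(1):.2f} deg, psi_9 = {tiny_golden_angle(9):.2f} deg")
params = SequenceParams()            # TR 3 ms, matrix 128, 7 slices, oversampling 1.28
nsp = nyquist_spokes_per_slice(params.n_readout)
print(f"fully sampled: {nsp} spokes/slice = {nsp * params.tr:.1f} s per slice")
sched = build_schedule(TrajectoryConfig(pattern="RSOS_PSI9",
                                        spokes_per_slice=nsp, sequence=params))
binning = bin_frames(sched, 6)
print(f"6 spokes/slice/frame -> {binning.frame_rate:.1f} fps, "
      f"{int(2 * binning.frame_rate)} fps with sliding window")

table = sweep_incoherence(["ASOS", "RSOS_PSI1", "RSOS_PSI9"], [6],
                          SequenceParams(matrix=64, n_readout=256, n_slices=7))
print(table.to_string(index=False))

scene = dynamic_swallow_phantom(matrix=64, n_slices=7, duration_s=5.0,
                                fps=12.35, seed=1)
metrics = compute_metrics(track_from_ground_truth(scene),
                          middle_slice=scene.grid[0] // 2)
print(metrics.to_frame().to_string())
```

prints

```
psi_1 = 111.25 deg, psi_9 = 18.71 deg
fully sampled: 402 spokes/slice = 1.2 s per slice
6 spokes/slice/frame -> 6.2 fps, 12 fps with sliding window
  pattern  spokes_per_slice  incoherence
     ASOS                 6    52.201117
RSOS_PSI1                 6    88.278731
RSOS_PSI9                 6    84.506578
                                          value
Duration (s)                           2.510121
Bolus (cm2)                            8.920000
Bolus (cm3)                           19.992000
Laryngeal elevation (mm)              20.000000
Contraction of submental muscles (%) -25.000000
```

Reading it: the tiny-golden-angle generator reproduces the analytic
angles; the sequence arithmetic gives the protocol's 402-spoke / 1.2 s
fully sampled reference and the 6.2 → 12 fps real-time rates; at six
spokes per slice both rotated patterns are substantially more incoherent
than the aligned one (52 → ~85–88, arbitrary grid-dependent units, only
the ordering matters); and the swallowing metrics recover the phantom's
programmed parameters (20 mm elevation, −25 % contraction, 20 mL bolus —
19.99 cm³ reflects the voxel quantisation) exactly from ground-truth
annotations.

The same pipeline runs from the shell, e.g.

```bash
starstack psf --pattern ASOS --pattern RSOS_PSI9 --spokes-per-slice 6 \
          --matrix 64 --out incoherence.csv
starstack phantom --seed 1 --out phantom.nii
starstack metrics --truth phantom.nii.truth.json \
          --masks phantom.nii.bolus_masks.nii --frame-rate 12.35 --out metrics.csv
```

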