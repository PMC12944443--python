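# seatvib

Visual–inertial decomposition of seated-occupant vibration.

When a person sits in a moving vehicle (tram, bus, train), the motion a
body-worn sensor records is a mixture: the seat shaking the body, the body's
passive compliance, the occupant's own postural corrections — and, if a
camera watches the scene, the camera's own jitter contaminating every
landmark it tracks. `seatvib` is a toolkit for pulling those layers apart
from three IMUs (seat, chest, camera) and an RGB-D landmark stream
(nose and both shoulders), for researchers in whole-body vibration (WBV),
ride comfort and seated-posture monitoring.

## What it computes

All rows of a session share one time base; a frame-level quality mask
`m(i) = m_IMU(i) ∧ m_RGBD(i)` (acceleration-norm spike gate at
`a_th = 30 m/s²`; landmarks defined, visible and within a 0–2 m depth band)
selects the samples every metric consumes. On that curated set:

- **Sliding RMS** per layer over a centred window of ΔT ≈ 2 s, with the
  local per-axis mean subtracted so gravity and drift do not contribute:
  `RMS(i) = sqrt( mean_{j∈W(i)} ‖a(j) − ā_W‖² )`.
- **Vibration transfer ratio** `VTR(i) = RMS_body(i) / RMS_seat(i)` —
  ≈1 passive transmission, <1 attenuation, >1 amplification — and the
  camera analogue on the *relative* acceleration `a_cam − a_seat`.
- **Passive gain** `k = ⟨a_body, a_seat⟩ / ⟨a_seat, a_seat⟩` (least squares
  on a passive segment), giving the **differential acceleration**
  `a_diff = a_body − k·a_seat`, band-passed to 1–20 Hz.
- **Body vibration velocity** by spectral integration:
  `V(f) = A_diff(f) / (j2πf)` for `f ≥ f_min = 0.8 Hz`, zero below, and
  `v(t) = F⁻¹{V(f)}`.
- **Postural compensation indices**: rotational
  `PCI_rot(i) = sliding RMS of ‖ω_body − k_rot·ω_seat‖`, and translational
  PCI per landmark — sliding RMS of the finite-difference velocity of each
  landmark's deviation from a neutral reference pose averaged over a short
  static interval.
- **Camera de-jittering**: the camera quaternion (logged, or re-estimated
  from the camera IMU by a Madgwick filter) is inverted on every landmark,
  `p_dejit = R_camᵀ p_cam`, then checkerboard extrinsics map the result to
  the world frame `p_w = R_ext p_dejit + t_ext`
  (x lateral, y vertical, z anteroposterior).
- **Axis-wise anisotropy** (percentage energy per axis of `a_diff` and of
  each landmark's compensation velocity) and **anthropometric consistency**
  (shoulder-width and nose–mid-shoulder deviations in mm) as skeleton
  quality checks.

Because real tram recordings cannot ship with a package, `seatvib`
includes a ground-truthed synthetic seated-rider simulator (seat excitation
spectrum, passive body coupling with known gain, camera mount dynamics and
rotational jitter, pose-tracker noise, injectable depth dropouts / depth
spikes / IMU spikes) so every stage is testable end to end.

## Worked example

```sh
seatvib simulate --seed 1355 --out demo        # 60 s tram-like session
seatvib mask demo/session.csv                  # frame retention tally
seatvib metrics demo/session.csv               # metric series + summary
seatvib report demo/session.csv --out demo/rep # full report tables
```

The mask tally for the clean default scenario keeps every frame:

```
 session  total_frames  kept  dropped  retention_pct  imu_gap  imu_spike  nan_depth  depth_out_of_range  low_visibility
sim-1355          1200  1200        0          100.0        0          0          0                   0               0
```

and the metric summary prints (abridged):

```
 session     k  mean_rms_seat  mean_rms_body  mean_rms_cam  mean_vtr  mean_pci_rot  e_sh_max_abs_mm
sim-1355 0.877          0.532          0.472         0.643     0.886         0.037            8.284
```

Read: the estimated passive seat→body gain is 0.877 (the scenario's true
gain is 0.9); the seat vibrates at 0.53 m/s² RMS and the body at 0.47 m/s²,
a mean transfer ratio of 0.89 (mild attenuation); the camera, on its
resonant window mount, exceeds the seat level; the reconstructed shoulder
width never deviates more than ~8 mm from the nominal under 2 mm tracker
noise. The axis-percentage table recovers the injected compensation
anisotropy — lateral-dominant nose sway, anteroposterior-dominant
shoulder sway:

```
  signal       P_x       P_y       P_z dominant
  a_diff 32.638064 34.182772 33.179165        y
pci_nose 66.206362 17.013365 16.780273        x
 pci_lsh 30.698259 31.091057 38.210683        z
 pci_rsh 30.194134 32.139159 37.666707        z
```

## Layout

- `src/seatvib/session.py` — data model, delimited-text session logs,
  multi-rate stream alignment
- `src/seatvib/mask.py` — quality gates and cause-coded tallies
- `src/seatvib/orientation.py` — Madgwick filter, de-jitter, extrinsics
- `src/seatvib/vibration.py` — sliding RMS, VTR, gain, band-pass,
  spectral velocity
- `src/seatvib/posture.py` — PCIs, axis-wise energies, anthropometrics
- `src/seatvib/simulate.py` — synthetic seated-rider generator
- `src/seatvib/pipeline.py`, `src/seatvib/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
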