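# Methods

This note records the models, parameter choices and known limitations
behind `seatvib`, in the spirit of a package methods appendix. It states
no empirical number that the test suite or `scripts/acceptance.py` does
not itself compute.

## Kinematic decomposition

The framework treats the seated scene as three quasi-rigid layers on a
common world frame (x lateral, y vertical, z anteroposterior):

1. **Seat excitation** `a_seat(t)`, `ω_seat(t)` — the platform input.
2. **Body response** `a_body(t)`, `ω_body(t)` — passive following of the
   seat with a scalar gain `k` plus the occupant's own compensation.
3. **Camera motion** `a_cam(t)`, `ω_cam(t)`, `q(t)` — mount-transmitted
   vibration plus rotational jitter that contaminates RGB-D landmarks.

This is a kinematic, not biomechanical, decomposition: `k` is a pragmatic
scaling constant identified by least squares on a passive segment, not a
subject-specific transfer function, and the compensation indices (PCI)
measure *relative* motion — they cannot separate active neuromuscular
control from passive seat–body compliance.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `a_th` | 30 | m/s² | conservative spike gate, far above rail-vehicle WBV levels but below IMU full scale; removes decode glitches without clipping real events |
| `z_min, z_max` | 0, 2 | m | plausible camera-frame depth band for a seated person facing the camera |
| `vis_min` | 0.5 | – | landmark visibility floor; pose trackers report confidence in [0,1] and 0.5 is the conventional accept threshold |
| `window` | 2 | s | spans several cycles of the 1–20 Hz band at both 100 Hz (IMU) and 15–30 Hz (camera) rates; shorter is noisier, longer smears transients; one length is used for *every* RMS-based metric so they stay comparable |
| `band` | 1–20 | Hz | the WBV-dominant range for seated occupants; suppresses quasi-static drift and mount/sensor noise |
| `f_min` | 0.8 | Hz | low cutoff for spectral integration; 1/f amplifies quasi-static content, and the comfort-relevant band for seated occupants starts around 0.8 Hz |
| `k` | estimated | – | closed-form least squares on ≥ 5 s of detrended passive data |
| `k_rot` | 1.0 | – | plain angular-velocity differencing; exposed because a scaled rotational transfer is equally defensible |
| `t_ref` | 2 | s | neutral-pose averaging interval (first seconds of mask-valid data); "short static interval" with no canonical length |
| `align_tol` | 0.02 | s | nearest-neighbour IMU matching tolerance, two IMU periods at 100 Hz |
| Madgwick `beta` | 0.1 | – | standard gradient-step gain; large enough to converge from a cold start in seconds, small enough not to chase accelerometer transients |

## Design choices where the design was open

- **Master timeline.** Aligned sessions are indexed by camera frames (the
  scarce stream; retention tallies then count camera frames). An IMU-rate
  master is equally supported. Note the consequence: a 1–20 Hz band needs
  `fs > 40 Hz`, so the spectral-velocity metric is computed on IMU-rate
  sessions and skipped (reported as undefined) on camera-rate ones.
- **Cause precedence.** A frame failing several gates is tallied once:
  alignment gap / IMU spike before missing depth before out-of-range depth
  before low visibility. Alignment losses get their own sub-code
  (`imu_gap`) inside the IMU class.
- **Window semantics.** Every windowed metric uses the same centred,
  per-sample-stride window; edge-truncated windows are computed but
  flagged. Detrending is per axis within the window (removing the vector
  mean, not the magnitude mean), which makes a constant offset contribute
  exactly zero. Masked-out records are excluded from window statistics
  rather than interpolated — the pipeline drops bad frames outright.
- **Spectral integration over gaps.** The FFT assumes uniform gap-free
  sampling, so the valid set is split into contiguous runs, each run is
  band-passed and integrated separately, and the velocities are
  concatenated; runs shorter than one window (or two periods of the lower
  band edge) are left undefined.
- **De-jitter reference.** Jitter is cancelled relative to the first valid
  orientation of the session, anchoring the de-jittered frame to the pose
  at which the extrinsics were calibrated. Only *rotational* jitter is
  compensated; translational camera motion is not subtracted from
  landmarks and remains a known limitation.
- **Orientation source.** Logged quaternions are authoritative when
  present; otherwise orientation is re-estimated from the camera IMU with
  an accelerometer+gyroscope Madgwick filter (gravity reference +y,
  Hamilton scalar-first quaternions, hemisphere-continuous output,
  gyro-only propagation on zero-norm accelerometer samples).
- **Axis-energy summaries.** The per-axis map is the self-consistent one
  (x←x, y←y, z←z). Body anisotropy averages per-axis sliding *RMS* values
  over windows fully inside valid runs; landmark anisotropy averages
  windowed squared energies of the compensation velocity, matching the
  energy (squared) definition for trajectories.
- **Division guards.** RMS ratios are undefined (NaN, never infinite)
  where the seat RMS falls below 1e-6 m/s²; gain estimation refuses
  near-zero seat energy.

## The synthetic rider: what it emulates, what it does not

The generator realises the decomposition as a generative model so that
every pipeline stage has known ground truth: a seat spectrum of sinusoids
(vertical-dominant, ≤ 10 Hz, typical of rail vehicles) with broadband
noise and boxcar event transients; body channels built as
`k_true·seat + compensation + noise`, with compensation displacements
generated in the world frame and differentiated *analytically* so
landmark and IMU channels stay mutually consistent; a camera with mount
gain, a mount resonance, and sinusoidal rotational jitter whose exact
quaternions are logged; landmarks as a rigid nose/shoulder triplet mapped
through the inverse extrinsics and the jitter rotation, with depth as the
camera-frame z; injectable, mutually disjoint artefacts (NaN depth,
out-of-range depth, IMU spikes) with exact-count or probabilistic
placement. Everything is deterministic under a fixed seed.

Landmark noise is AR(1)-correlated (stationary sd 2 mm, lag-one
correlation 0.95): pose trackers smooth temporally, so their error is far
from white. This matters because translational PCI differentiates
positions at frame rate — white noise of the same amplitude would imply
velocity noise an order of magnitude above anything a smoothed tracker
produces.

Not emulated: photorealistic imagery or a real pose estimator (only its
output statistics), clock drift between devices, translational camera
jitter, route/track geometry, and a sensor-frame camera accelerometer
(the logged camera acceleration is world-aligned; orientation ground
truth comes from the logged jitter quaternions). Consequently, passing
tests demonstrate the *pipeline's* correctness — recovery of injected
gains, axes, geometry and bookkeeping — not the field accuracy of pose
estimation or the biomechanical fidelity of any particular vehicle.

## Validation scenarios and problem sizes

The validation suite uses: 1,000-sample random fixtures for brute-force
oracle equivalence; 20 s at 100 Hz for the analytic spectral-integration
checks; 10 s sessions for noiseless gain recovery, de-jitter efficacy
(±2° at 3 Hz jitter) and degenerate-scenario identities; 100-frame
sessions for exact mask bookkeeping; and 100 seeded 30 s sessions (nose
lateral sway 15 mm at 0.5 Hz, shoulder anteroposterior sway 12 mm at
0.4 Hz, default tracker noise) for the dominant-axis recovery rate.
These sizes give sub-percent estimator variability while keeping the
whole suite and the acceptance script in the seconds range.

## Known limitations

- PCI conflates passive compliance and active control by construction.
- Rotational-only de-jittering leaves translational camera motion in the
  landmark trajectories.
- The spike gate validates gyroscopes only implicitly (through the
  acceleration mask); a gyro-specific fault that leaves accelerations
  clean would pass.
- Frequency-weighted comfort indices (ISO 2631 / AS 2670 weightings, VDV,
  MTVV) and frequency-domain transmissibility curves are out of scope;
  the decomposed signals are suitable inputs for them.
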