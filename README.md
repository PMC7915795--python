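# handkin

Hand motion kinematics toolkit: converts per-frame bone orientation bases
(elbow to fingertips) into per-joint Cardan angle time series relative to a
neutral-zero posture, exports the motion as Biovision Hierarchy (BVH) files
and joint-driver vector files for musculoskeletal simulation, and validates
the angles against 2D marker tracks. A forward-kinematics synthetic
generator stands in for the hardware hand-tracking sensor.

## Concepts and conventions

* **Skeleton** — 22 bones in a tree rooted at the forearm:
  forearm → hand → per digit (1=thumb … 5=pinky) metacarpal → proximal →
  intermediate → distal. The thumb keeps the uniform four-bone chain with a
  zero-length metacarpal; its articulated joints are exposed as CMC/MCP/IP.
  17 articulated joints: elbow (flexion + rotation), wrist (flexion +
  abduction), and three chain joints per digit.
* **Basis** — a bone's orientation is a 3×3 orthonormal matrix whose
  **rows** are the bone's local axes in the global frame: X = flexion axis,
  Y = abduction axis, Z = longitudinal axis pointing distally. At the
  neutral-zero posture (flat outstretched hand) every basis is the identity.
* **Angles** — a joint's rotation relative to neutral-zero is
  `parent_rel @ child_rel.T`, where each `*_rel` is `B(t0) @ B(ti).T` for
  that bone. Cardan angles (φ, θ, ψ) = (flexion, abduction, rotation), in
  degrees, are extracted under the fixed intrinsic factorization
  `R = Rx(φ) · Ry(θ) · Rz(ψ)`; finger flexion (curling toward the palm) is
  positive. Frame 0 is the reference unless an explicit reference posture
  is supplied. Series are unwrapped (no ±360° jumps).
* **BVH dialect** — channel order `Zrotation Xrotation Yrotation` (root
  additionally carries XYZ position channels); the Cardan triples are
  genuinely re-expressed as intrinsic Z-X-Y angles so third-party players
  reproduce the rotation. Offsets in mm, rotations in degrees, 6 decimal
  places. Frames are 0-based; slices are half-open `[start, end)`.
* **Driver files** — one file per body part (`Finger1.any` … `Finger5.any`,
  `Wrist.any`, `Elbow.any`) with one vector per joint per enabled degree of
  freedom, e.g. `Finger2.Joint_PP_IP.Flexion = {0.000000, …};`, values in
  **degrees**; plus `TimeSeries.any` (evenly spaced 0…1, one value per
  frame) and `FingerLength.any` (per-digit segment lengths in mm, from
  frame 0 by default, mean-over-frames optional for noisy input).
* **Recording file** — plain text, self-describing
  (`format handkin-recording 1` header, skeleton block, then per-frame
  bone lines: position + 9 row-major basis scalars); `#` lines are
  comments. See `src/handkin/recording_io.py` for the exact grammar.

## CLI

```bash
# synthetic fist-closing recording, 100 frames at 60 Hz (deterministic by seed)
handkin generate --frames 100 --frame-rate 60 --seed 1 \
    --out fist.rec --ground-truth truth.any

# recording (or BVH) -> driver files and/or BVH, with optional frame slicing
handkin convert fist.rec --out-dir drivers/ --bvh-out fist.bvh
handkin convert fist.bvh --out-dir drivers_from_bvh/ --start 10 --end 60

# compare two angle trajectories (marker CSV, recording, or BVH)
handkin compare fist.rec fist.rec --project-b side --out report.csv

# summaries and a text frame dump
handkin info fist.rec --dump-frames 5
```

Every subcommand accepts `--config FILE` (`key = value` lines mirroring the
flags; explicit flags win). Logs go to stderr, results to files. Exit
codes: 0 success, 1 processing error, 2 usage error.

## Layout

```
src/handkin/
  skeleton.py      bone tree, joints, neutral-zero reference posture
  kinematics.py    rotation algebra, Cardan extraction, angle series
  recording_io.py  plain-text recording format
  synthetic.py     forward kinematics, fist scenario, sensor-noise model
  bvh.py           BVH reading/writing/slicing
  drivers.py       driver vectors, time series, finger lengths
  validation.py    2D marker angles, projection, trajectory comparison
  cli.py           generate / convert / compare / info
tests/             unit, property (hypothesis) and acceptance tests
scripts/acceptance.py
```
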