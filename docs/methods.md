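# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Skeleton model and conventions

The skeleton is a tree of 27 joints and 26 edges over the standard
33-landmark full-body pose with the four inner/outer-eye refinement
landmarks and the two mouth landmarks removed.  The joint list and edge set
are single documented constants (`skeleton.LANDMARK_TO_JOINT`,
`skeleton._EDGES`); alternative reductions are one edit away.  The tree is
rooted at the **left hip** — the root must itself be a landmark for the
graph to keep exactly 27 vertices — and the traversal order places the two
body axes immediately after the root (right hip, then left shoulder) so that
body-fixed reference frames are available to every later joint, followed by
the left arm, right arm, head chain, right leg and left leg.  Coordinates
are right-handed, meters, +y up; world +z is north, +x east; frame indices
are 0-based.

## Feature representations

*Spherical convention*: ρ is the radial distance, φ the polar inclination
from +z in [0, π], ψ the azimuth from +x in (−π, π].  Offsets from each
joint to its tree parent are measured in **global axes** by default (the
simplest reading of a per-parent spherical origin); a `local_frames` option
expresses them instead in a body-fixed frame whose z-axis lies along the
bone arriving at the parent and whose in-plane reference is the pelvis line
(fallback: torso axis, then global axes when near-parallel, threshold
1e−3 on the orthogonal residual).

The choice matters for invariance: with global axes, a rigid rotation of
the whole body changes *every* joint's angles, so rigid-motion invariance
holds only for the body-fixed option — and there, only bones whose parent
hangs directly off the root (measured in global axes by construction)
respond to a global rotation.  The rotation-adjacency representation maps
each parent bone direction onto the child bone direction by the
minimal-angle rotation; under a global rotation R the quaternion is
conjugated by R, so its rotation *angle* is invariant while its axis
co-rotates.  The property tests check exactly these statements.  Exactly
anti-parallel consecutive bones have no unique minimal rotation; the
documented tie-break is a half-turn about global +y.

The fixed-ρ variant drops the 27 radial entries only (no angle
re-normalisation), giving the 54-dimensional per-frame vector used as the
default model input; inversion then requires per-bone lengths, for which
the per-sequence median bone lengths are the natural supply.

## Synthetic protocol

The generator emulates a two-camera laboratory protocol: for each of 3
subjects, one 60 s / 24 fps sequence per (6 ADLs × 3 directions × 4 camera
heights) — 72 sequences and 103,680 frames per subject, 311,040 frames in
all, 10,368 non-overlapping 30-frame windows (576 per ADL per subject).
Abnormal variants of the gait-bearing activities (WLK, HSK) are emitted as
additional tagged sequences and never counted in the normal-protocol
arithmetic.

Motion is a phase-coupled sinusoidal oscillator: ankle lift follows
½(1−cos θ) with left/right legs in antiphase, stride displacement sin θ,
pelvis bob at twice the stride frequency, and arm counter-swing (suppressed
for housekeeping, where both hands grip the broom and sweep together with a
torso yaw).  Seated activities (EAT, DRN, DRS) share a seated posture but
differ in arm kinematics and signature postures: fast small bilateral
hand-to-mouth arcs over a table (EAT, 0.45 Hz), a slow raise–dwell–lower
drinking cycle with a raised glass hand and head tilt (DRN, 0.12 Hz), and
broad bilateral dressing arcs with a forward-pitched trunk (DRS, 0.25 Hz).
SLP is a supine posture with 0.25 Hz breathing motion.  All joints carry
1.5 mm Gaussian observation noise.

*Abnormality injection*: asymmetry_gain scales the left leg's amplitudes
(the pelvis-referenced left/right ankle-excursion ratio then equals the
gain), tremor adds narrow-band distal jitter with a slow amplitude
envelope, rigidity_rom_scale shrinks all oscillation amplitudes, sway_amp
adds 0.35 Hz lateral torso oscillation, slowdown_factor stretches the gait
period, stop_go_rate inserts Poisson-timed 0.6–1.2 s zero-velocity holds,
and limp_phase_offset perturbs the left leg's phase.  No magnitudes are
prescribed anywhere, so the default abnormal profile (gain 0.6, 2 cm 5 Hz
tremor, 0.7 range-of-motion, 4 cm sway, 1.3× slow-down, 4 holds/min,
0.6 rad limp) was chosen once to represent a clearly pathological gait
while remaining kinematically plausible; every field is config-exposed.

*Subjects* differ by fixed styles in scale, cadence (0.68/0.80/0.95 Hz),
stride and arm-swing factors, habitual trunk pitch and arm carriage.
Differences are deliberately expressed in joint-angle space, not only body
scale, because the fixed-ρ angular features normalise scale away almost
entirely; without angle-space differences no representation-level
inter-subject signal would exist for the intra- vs inter-class comparison.

*Cameras*: the two cameras sit 5 m apart, each yawed 45° so the optical
axes cross at the scene centre; the camera frame keeps +y up and +z along
the optical axis.  A capture is *frontal* when the walking azimuth is
within 45° of the optical axis; the exact-45° tie (direction N) resolves to
camera 1 frontal / camera 2 lateral.  The twelve one-minute recordings per
activity are realised as the 12 (direction × height) configurations.
24 fps is the generator default; a 20 fps real-time acquisition floor is an
operational requirement outside this package's scope.

## Models and training

All three networks run on the in-package numpy autodiff core (`gaitadl.nn`:
reverse-mode graph, fused dilated-causal-convolution and
softmax-cross-entropy kernels, Adam).  Gradients are verified against
central differences in the test suite.

*TCN*: K residual blocks (valid range 3–5), each two weight-normalised
dilated causal convolutions with the block's dilation 2^(k−1), ReLU and
dropout, and a residual add (1×1 projection on channel change).  Default
hyperparameters: 4 blocks of 128 filters, kernel sizes (8, 5, 13, 8),
dropout (0.5475, 0.1491, 0.005, 0.6214) — taken as given constants, not
re-optimised.  The readout is the last timestep (causally consistent;
mean-pool available).  The closed-form receptive field assumes one
convolution per level and a uniform kernel size; since the default blocks
mix kernel sizes, `receptive_field` returns the general telescoped sum in
that case and flags that the closed form does not apply.

*GRU*: 4 stacked layers of 125 hidden units by default; the update gate
weights the candidate state exactly as the printed recurrence (some GRU
variants swap z and 1−z; this one is implemented as stated).  Final hidden
state of the top layer feeds the head; no inter-layer dropout.

*LSTMAE*: three bidirectional LSTM layers with per-layer linear projections
— (256→200), (128→100) bottleneck, (256→200) — and a final linear map back
to the feature dimension; the temporal axis is preserved end to end.
Defaults exist for both feature sources (TCN and GRU activations, which are
the classifier's penultimate per-timestep activations; config-exposed).
Input features are standardised with training-set statistics stored on the
detector.  The T×F activation matrix flattens time-major into the RE sum.

*Shared training harness*: stratified 70/15/15 split, Adam at lr 1e−3,
early stopping on validation accuracy (classifiers, patience 10 of ≤100
epochs by default) or validation reconstruction error (autoencoder,
patience 20 of ≤200), best-state restoration.  Classifier inputs are
standardised per feature with training-split statistics stored on the
model.  The detector threshold is the 95th percentile of validation-normal
reconstruction errors; training accepts only normal-tagged windows and
enforces the intra/inter subject-provenance constraint, so no abnormal
label can leak into detector training by construction.

One integer seed drives everything (split, shuffling, dropout,
initialisation, generator); per-stage child seeds derive by SHA-256
hashing, and repeated runs are bit-identical.

## Problem sizes in the test suite

The suites run the study at reduced sizes chosen as the package's own
standard smoke-scale conditions: ~720-window recognition sets from one
subject, 32-filter 3-block TCNs and 2×48 GRUs, a (16, 8, 16)-unit
autoencoder, and a one-cell three-subject protocol for detection (40
training windows per detector, validation fraction 0.3 so the threshold
quantile rests on 12 rather than 6 windows).  The intra- vs inter-class
comparison uses size-matched training sets (the inter pool is subsampled to
the intra size) so the comparison isolates data *provenance* rather than
data volume.  Model configuration defaults remain the full-size constants.

## What passing tests do and do not show

The generator produces clean, strongly separable classes and strongly
injected abnormalities; near-perfect recognition accuracy and detection
AUROC on it demonstrate that the pipeline is implemented correctly and that
the semi-supervised protocol behaves as designed (intra-class training
beats inter-class because the inter detector both reconstructs the
monitored subject's normal gait worse and calibrates its threshold on the
wrong normal distribution).  They do not demonstrate performance on real
depth-camera data: the simulator has no occlusion, no depth noise model, no
pose-estimation failure modes, no within-subject day-to-day variability,
and its abnormalities are parametric rather than pathological.  The
external pathological-gait dataset loader is interface-only for the same
reason: the data are not redistributable and use a different 25-joint
topology.

## Known limitations

- Walking progression reverses direction without turning the body
  (sinusoidal back-and-forth), a simplification that avoids modelling
  turns; camera-view semantics are unaffected.
- The anti-parallel-bone tie-break and the near-parallel reference
  fallbacks in body-fixed frames are measure-zero discontinuities.
- `receptive_field` describes one convolution per level; the built blocks
  contain two, so the architecture's true receptive field is larger than
  the closed form suggests.
- Multiclass SEN/SPE/PRE are one-vs-rest macro averages; undefined ratios
  are reported as NaN with flags, and macro averages skip them.
- The camera-setup sweep retrains per cell (the stricter reading of a
  per-setup comparison); with the noise-free generator all cells are easy,
  so the sweep's argmax is only meaningful when cell difficulty differs
  (as in the planted-optimum test).
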