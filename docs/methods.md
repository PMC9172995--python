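# Methods

This note documents the models, conventions, and numerical choices behind
each analysis surface, what the synthetic generators do and do not emulate,
and the known limitations.

## Video tracking

Frames are 8-bit grayscale. Each frame is divided elementwise by a
background image recorded without the animal; a pixel belongs to the body
mask when its ratio deviates from 1 by more than `deviation_tol`
(default 0.1 — under 8-bit quantization a tolerance of 0 would flag nearly
every pixel). The animal's position is the centroid of the largest
8-connected mask component with at least `min_blob_px` pixels; component
area times the pixel area gives the body area. Frames without a qualifying
component get linearly interpolated positions (copied from the nearest
valid frame at the record ends); interpolation never extrapolates.

Coordinates: image origin at the top-left pixel center, x rightward along
columns, y downward along rows, in millimeters (`mm_per_pixel` scale);
frame indices are 0-based and time is index / frame rate.

Speed is the distance between temporally adjacent positions multiplied by
the frame rate (15 Hz by default), one value per frame pair.

Freezing: a frame pair is flagged when the body moved by less than
20 mm² (strict inequality). "Moved by" is the area of the symmetric
difference of the two body masks — the reading under which a motionless
animal scores near zero. The alternative reading (absolute change of mask
area) is available via `rule="area_change"`; it cannot distinguish a
translating animal from a still one and is off by default.

## Fine-scale cumulative profiling

For each subject, T(x) is the cumulative time (or probability) of
occupying stressor-axis positions ≤ x, and U(v) the cumulative probability
of frame-pair speeds ≤ v, both evaluated on a shared grid (defaults: 5-mm
spacing over the axis range; 5 mm/s for speeds). The stressor axis is a
unit vector with its origin at the door / maze center / field center /
chamber face; the coordinate increases toward the stressor-free region, so
T(0) reads off the time spent on the stressor side. Speed profiles can be
restricted to a named zone; a frame pair belongs to the zone of its first
frame.

At every grid point the two groups' per-subject values are compared with a
two-tailed two-sample t-test (pooled variance by default, Welch via
`equal_var=False`), displayed as −log10(p) (base 10; the conventional
significance display). Bins where both groups are constant have no defined
test: p is set to 1 when the means agree and to the machine-minimum float
when they differ, and the bin is flagged `degenerate`. The per-bin scan is
descriptive — no correction for multiple comparisons is applied across
bins, and neighboring bins are strongly dependent by construction. The
collapsed five-number summary (min, Q1, median, Q3, max) uses the
linear-interpolation quantile convention.

Calibration behavior: under a null two-group design (8 subjects per group,
300 s at 15 Hz) the fraction of non-degenerate bins with p < 0.05 measures
≈ 0.04 — slightly conservative, because bins near the occupancy extremes
take near-discrete values across subjects. Degenerate (fully saturated)
bins are excluded from that rate, since their policy p-values are not test
outcomes.

Zone metrics: dwell time by frame membership in named rectangular zones; a
transfer is a membership change between consecutive frames (frames outside
every listed zone inherit the previous membership so a brief unassigned
position does not double-count a crossing); the latency to the first
transfer is censored at the recording duration.

## Behavioral state space and likelihood classifier

The state at an interior frame i is (axis position, speed, signed axis
velocity, acceleration magnitude), built from forward-difference
velocities v_i = (p_{i+1} − p_i) × frame rate and acceleration
|v_i − v_{i−1}| × frame rate; a record of n frames yields n − 2 states.

The classifier is a feedforward network 4 → 26 → 30 → 24 → 3 with
log-sigmoid hidden units. The output layer is a softmax — cross-entropy
training with probability outputs requires a normalized output, and the
three class probabilities must sum to 1 (a per-unit sigmoid output is
available behind a flag for scoring). Features are z-scored with
training-split statistics before entering the network: the four inputs mix
mm, mm/s, and mm/s² and are ill-conditioned raw; this also makes results
invariant to affine rescaling of the input units.

Training is full-batch scaled conjugate gradient (Møller 1993) on the mean
cross-entropy, with an 80/20 random train/test split (`split_seed`) and
small-uniform weight initialization (`init_seed`; the two seeds are
independent configuration keys). Training stops at the first of:

1. 1,000 iterations (configurable `max_iter`);
2. zero mean squared error of the output probabilities against the
   one-hot targets;
3. held-out error rate strictly increasing for more than 6 consecutive
   epochs (there is no third validation split; the 20% test split plays
   this role);
4. training-objective gradient norm below 1e-7;
5. the SCG scale/regularization parameter λ exceeding 1e10 — the only
   monotone "gain" quantity in this optimizer; a diverging λ means the
   quadratic model has stopped making progress.

The local likelihood of one state is the network's probability triple; the
global likelihood of a recording is the arithmetic mean of its local
triples, classified by argmax with ties broken to the lowest class index.

## Ultrasonic vocalization detection

The recording (250 kHz sampling) is cut into non-overlapping 0.4-ms
windows (100 samples) and each window is Fourier transformed with a
rectangular window by default (Hann behind a flag); the one-sided
periodogram gives PSD in power per Hz, expressed in dB relative to a
configurable reference (default 1.0). The absolute −75 dB/Hz threshold of
the original recording chain depends on its calibration, so the threshold
and reference are configuration defaults, not calibrated constants.

A window is a vocalization candidate when *any* PSD bin reaches the
threshold (an all-bin rule would never fire for narrowband calls).
Maximal contiguous candidate runs become segments; a segment is rejected
when its average 0–50 kHz PSD exceeds its average 50–120 kHz PSD
(low-frequency noise). No gap merging and no minimum duration are applied
by default; both are available. At 250 kHz sampling the Nyquist frequency
(125 kHz) covers the 120-kHz band edge; the spectrogram refuses sample
rates that do not put an integer number of samples in a 0.4-ms window.
Segment edges are quantized to whole windows, so a chirp's duration is
recovered to within ±2 windows (±0.8 ms).

## Diffusion tensor imaging

The brain mask keeps voxels whose mean diffusion-weighted intensity is at
least half the global mean of those per-voxel means, then removes
6-connected clusters smaller than 10 voxels.

Tensors are estimated per voxel by ordinary least squares on
log-intensities against the 7-parameter Stejskal–Tanner design (ln S0 and
the 6 unique tensor components), using all measurements including the b=0
rows (they are regression rows, not a separately averaged baseline). No
signal weighting is applied. Eigenvalues are sorted descending; negative
fitted eigenvalues are clamped to zero with a per-voxel flag. Scalar maps:
MD = (λ1+λ2+λ3)/3, AD = λ1, RD = (λ2+λ3)/2, FA =
sqrt(3 Σ(λi−⟨λ⟩)² / (2 Σλi²)), defined as 0 where all eigenvalues vanish;
with clamping, FA ∈ [0, 1] and MD/AD/RD ≥ 0 everywhere.

Tracking: physical coordinates put voxel centers at (index + 0.5) × voxel
size. From each seed voxel, two start points ("two samplings") are
jittered uniformly within the voxel from a seeded generator; integration
proceeds bidirectionally along the principal eigenvector in fixed 50-µm
steps with trilinear interpolation of FA and of e1 (eigenvector signs are
aligned to the previous step direction before averaging; nearest-neighbor
sampling behind a flag). A direction terminates on leaving the mask, FA
dropping below 0.4, a turning angle above 57.3° between consecutive
steps, or reaching half the 75,000-µm length ceiling; streamlines shorter
than 750 µm are discarded. Given the jitter seed, tracking is fully
deterministic.

## Assay statistics

Tukey's range test follows a one-way ANOVA: q_ij = |mean_i − mean_j| /
sqrt(MSE/2 · (1/n_i + 1/n_j)) (the Kramer form; with equal n this is
|Δmean|/sqrt(MSE/n)), with adjusted p from the studentized-range
distribution (k groups, within-group df) evaluated by numerical
integration (scipy's implementation; target accuracy well below 1e-6).
Zero within-group variance with unequal means reports the machine-minimum
p with a warning.

One-tailed Mann–Whitney U uses exact enumeration for combined n ≤ 12
without ties and the normal approximation with midrank tie correction
otherwise; the exact path refuses ties (it falls back to the
approximation with a warning).

Bootstrap standard errors resample subjects with replacement (each
resample the size of the original sample, 10,000 resamples by default);
the SE is the standard deviation of the resampled statistics. The default
statistic is the percentage mean, covering both percentage-of-animals
(binary indicators) and per-category percentage-of-time (composition rows)
summaries.

The 4PL standard curve ρ(X) = d + (a−d)/(1+(X/c)^b) maps blank-subtracted
optical density X directly to concentration; fitting uses bounded
least squares initialized with a and d from the extreme-X responses,
c at the X nearest the mid-response, and b = 1. Rows with X ≤ 0 cannot
enter the power term and are excluded with a warning. Concentration
read-out is a direct curve evaluation; samples outside half-to-double the
calibrated OD range are flagged as extrapolation.

## Synthetic generators: what they emulate, and what they do not

- **Trajectories** are a reflected Ornstein–Uhlenbeck process around a
  group anchor (relaxation 0.5 s⁻¹, per-step noise 5 mm at 15 Hz, 300 s,
  8 subjects/group by default — matching the study design's recording
  geometry). The implanted spatial-preference effect displaces group B's
  anchor along the stressor axis by a known amount; the speed effect
  scales group B's step noise. The OU choice gives stationary, bounded,
  autocorrelated paths with tunable first/second moments — it is a
  testbed, not a model of mouse kinematics: no thigmotaxis, rearing,
  grooming bouts, or social interaction. Passing calibration on OU data
  shows the scanner's statistics are correct, not that real trajectories
  satisfy the t-test's assumptions.
- **Frame stacks** render an anti-aliased dark disk (0.5× background) on a
  uniform background — sufficient for the ratio-mask tracker, with none of
  the illumination gradients, shadows, or body-shape changes of real
  video.
- **Audio** is white noise plus cosine-tapered pure-tone chirps; real
  calls are frequency-modulated syllables.
- **DWI phantoms** follow the noiseless Stejskal–Tanner forward model
  exactly (b = 2000 s/mm², 30 electrostatic-repulsion directions + 5 b=0
  rows); optional noise is additive Gaussian on the magnitude signal —
  Rician noise, eddy currents, and partial-volume effects are not
  simulated.
- **State streams** are Gaussian per class; **ELISA plates** invert the
  4PL exactly, with duplicate wells, a blank offset, and optional Gaussian
  OD noise. Standards lying exactly at a 4PL asymptote have no finite OD
  under the printed equation; the generator's default parameters place
  both asymptotes beyond the standard series, and asymptote-valued
  standards otherwise saturate at a configurable plate-reader ceiling and
  are flagged.

All generators are bit-reproducible under a fixed seed. Trajectory groups
draw independent child seeds from the spec seed so two-group statistics
are valid; an explicit `group_seeds` override can make a null
configuration produce bit-identical groups.

## Problem sizes used in the shipped checks

The acceptance script simulates 200 null and 100 shifted two-group
studies (8 subjects/group, 300 s at 15 Hz), one 4×4×4 tensor-recovery
phantom plus a 5×5×40 tracking phantom, a 1,200-sample classifier
training with 100 recording-level recovery trials, a 0.6-s audio record
with three chirps, and a 6-standard duplicate plate — sizes chosen so the
whole script completes in well under a minute of simulation per stage
while keeping Monte-Carlo standard errors small relative to the bands
being checked.

## Known limitations

- The scanner's per-bin t-test treats subjects as exchangeable units and
  bins as descriptive; it is not a corrected hypothesis-testing family.
- The USV detector's absolute dB threshold is only meaningful relative to
  the configured reference level.
- Tractography is deterministic single-tensor streamlining; crossing
  fibers and probabilistic methods are out of scope.
- The EPM's cross geometry is carried by zones; its 1-D stressor axis is
  taken along the closed-arm direction.
- Atlas registration and region-wise group statistics on real brains are
  out of scope, as are pose estimation and manual event scoring.
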