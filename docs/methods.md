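# Methods

## Model and procedure

`stridedtw` treats stride segmentation as subsequence template
matching.  A fixed-length stride template *T* (M = 200 samples,
one trace per sensor axis) is warped non-linearly onto a continuous
movement sequence *S* (N samples) by dynamic programming.  The
per-axis local distance is the squared sample difference
D(m, n) = (t_m − s_n)²; multi-axis operation sums the per-axis
distance matrices element-wise *before* accumulation, so the warping
path is shared across axes (this differs from summing per-axis DTW
costs, which would allow each axis its own alignment).  The
accumulated cost matrix C is filled bottom-to-top with the standard
three-neighbour recurrence; its first column is the running sum of
D's first column, which penalises alignments pushed against the left
edge of the recording.  The top row of C is the distance function
Δ(n): the minimal cost of warping the complete template onto a
subsequence ending at sample n.  Stride-end candidates are local
minima of Δ below a threshold τ; backtracking from (M−1, n) to row 0
recovers the warping path, whose final column is the stride start.

Candidates are then filtered: duration strictly inside
(250, 2000) ms, and — visiting candidates in ascending cost order —
overlap with every already-accepted segment below 100 ms.  Both
borders of a stride are the negative sagittal-gyroscope (GZ) troughs
flanking the swing phase, so consecutive strides may share a border
sample; a one-sample overlap (~10 ms at 102.4 Hz) is always
admissible.

The comparison baseline detects swing-phase peaks on raw GZ: 3-point
local maxima above 150 °/s, thinned greedily by descending amplitude
until all survivors are ≥ 250 ms apart.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| template length M | 200 | samples | common length strides are resampled to before averaging |
| accel / gyro range | 6 / 500 | g, °/s | normalization divisors putting all axes on [−1, 1] |
| τ | tuned (grid 5–130, step 5) | dimensionless | cap on accumulated warping cost; sensitivity dial |
| axes | GY, GZ | — | sensor axes whose distance matrices are summed |
| min / max stride duration | 250 / 2000 | ms | plausibility window, strict inequalities |
| max overlap | 100 | ms | pairwise overlap cap between accepted segments |
| border tolerance | ±100 | ms | match window for evaluation (~10 % of a stride time) |
| peak gate / separation | 150 / 250 | °/s, ms | baseline amplitude and refractory constraints |

τ is on the normalized-cost scale and grows with the sampling rate
(more samples, more summed cell costs), so τ values are only
comparable at a fixed fs.  The harness never compares τ across
recordings with different sampling rates.

## Numerical choices

- **Local minimum of Δ**: strictly smaller than both neighbours;
  plateaus count once at their leftmost column when both flanks are
  larger; array boundaries qualify when the single neighbour is
  larger.  Duplicate minima on one physical stride are left to the
  overlap constraint downstream.
- **Backtracking tie-break**: diagonal step first, then vertical,
  then horizontal — prefers the shortest, most time-faithful warp.
- **Constraint resolution**: on an overlap conflict the costlier
  candidate is dropped, consistent with the method's similarity
  logic.
- **Durations** are compared in milliseconds with strict
  inequalities, computed exactly as (end − start)·1000/fs.
- **Degenerate metrics**: empty detections vs empty labels score
  precision = recall = F = 1; any other zero denominator scores 0;
  when precision equals recall the F-measure is returned as that
  value exactly (the harmonic mean of equals), avoiding float
  round-off.
- **Matching** is greedy one-to-one in start order.  Optimal
  assignment was not used: within a ±100 ms gate double-match
  conflicts are rare, and greedy matching is deterministic and easily
  audited.  Pooled-counts metrics and mean-of-dataset metrics are
  both reported, since they differ in general.
- **Template averaging** sums per-sample values in sorted order, so
  the template is exactly invariant under permutations of the input
  strides.  Resampling precedes averaging; normalization follows it
  (the two commute for fixed range constants).
- **Files** are written with 17-significant-digit floats and read
  back with round-trip float parsing, so write→read is bit-exact.
- The DP kernel is JIT-compiled with numba when available, with an
  identical pure-Python fallback (same operation order, identical
  results).

## The synthetic generator

The generator emulates the stride morphology of straight walking as
recorded at the lateral heel: a dominant positive GZ swing peak
(450 °/s at unit amplitude) flanked by two negative border troughs
(−200 °/s), smaller correlated lobes on the other five axes.  All
waveforms are sums of Gaussian/sinusoidal lobes with hand-set
positions; a stride of any duration is a pure time-scaling of the
same shape.  Walks draw stride durations from a truncated normal
(mean 1000 ms, SD 100 ms, clipped at ±3 SD — i.e. 700–1300 ms, safely
inside the plausibility window), jitter per-stride amplitude
multiplicatively (SD 5 %), and add white noise expressed in
normalized units (SD 0.01, i.e. 5 °/s on gyro axes) after the
amplitude scale is fixed.  Confounder blocks provide the classic
failure material: `stairs` (periodic single-lobe GZ bursts above the
150 °/s gate, no border troughs), `turning` (sustained high GY), and
`rest`.  A single seeded `numpy.random.default_rng` stream with a
fixed draw order (per stride: duration, then amplitude; finally one
noise draw) makes generation bit-reproducible.

What the generator does **not** emulate: inter-subject morphology
differences, slow drift and baseline wander, sensor misalignment,
gait initiation/termination transients, pathological gait (festination,
shuffling), or genuine stair-climbing kinematics.  Passing tests on
this material therefore demonstrate the algorithm's mechanics —
recovery under time/amplitude warping and rejection of
shape-dissimilar periodic motion — not clinical-grade performance on
real cohorts.  Cohort-shaped report tables (`stridedtw.reports`) are
provided so a real labeled dataset can be evaluated with the same
harness.

On this synthetic material the stride-vs-confounder margin is wide:
true strides align at costs ≈ 0.03–0.1 (GY+GZ, mild jitter and
noise), stair blocks no lower than ≈ 7, and rest blocks ≈ 22, so the
cross-validated τ settles at the bottom of the grid.  Real
recordings, with their within-subject variability, push optimal τ
well into the grid's interior — which is why the grid extends to 130.

## Problem sizes

The test suite and `scripts/acceptance.py` use walks of 6–20 strides
(~10–35 s at 102.4 Hz), cohorts of 2–5 subjects, 50–200 random
matrices (M ≤ 6, N ≤ 12) for the exhaustive-enumeration oracle, and a
template built from 75 labeled strides of 5 subjects.  These sizes
exercise every code path while keeping a full run in seconds.

## Design choices on genuinely open points

- Left/right-foot axis harmonization is a user-supplied per-axis sign
  map (`invert_axes`), not a hard-coded rule, since mounting
  conventions vary.
- Warping-path steps are stored as index *decrements* from stride end
  to stride start — the path is searched backward in time.
- Cross-validation resolves τ ties toward the smallest τ (fewer
  spurious detections); fold-mean metrics are reported alongside
  pooled-counts metrics.
- Evaluation matching is one-to-one for segments; a baseline peak
  can only credit one label.
- Normalization is pure division by the range constants, without
  clipping: samples beyond the nominal range (sensor saturation)
  keep magnitudes above 1, preserving information.

## Known limitations

- The template is a single global average; populations whose stride
  shape differs from the template (e.g. much older or impaired
  walkers) need higher τ and lose precision — a per-group or
  individualized template is the natural extension.
- τ must be re-tuned per sampling rate, axis set and population.
- Segmentation is offline and single-pass; there is no streaming
  mode.
- The method delimits strides only; gait events inside a stride
  (heel strike, toe off) and stride parameters are out of scope.
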