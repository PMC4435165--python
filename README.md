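# stridedtw

Stride segmentation of foot-worn inertial sensor recordings by
**multi-dimensional subsequence dynamic time warping (msDTW)**.

Sensor-based gait analysis — for elderly fall-risk screening, for
Parkinson's disease monitoring, for any clinical question that rides
on stride-by-stride parameters — starts with one unglamorous problem:
cutting a continuous shoe-mounted accelerometer + gyroscope recording
into individual strides, while *not* cutting out stair climbing,
turning, or any other periodic movement that merely looks fast.
`stridedtw` solves this by warping a reference stride template
non-linearly onto the recording, so strides of different durations and
amplitudes are found wherever the *shape* matches, and everything else
is rejected.  A classical amplitude-gated peak-detection baseline, a
full evaluation harness and a synthetic gait generator with exact
ground-truth labels are included.

## The method

A recording is a sequence *S* = (s₀, …, s_{N−1}) of 6-axis samples
(AX, AY, AZ in g; GX, GY, GZ in °/s; ~102.4 Hz).  A stride template
*T* = (t₀, …, t_{M−1}) (M = 200 samples) is the sample-wise mean of
many manually labeled strides, each linearly resampled to length M.
Both are normalized by the sensor ranges (±6 g, ±500 °/s) so axes can
be combined.  Then, per selected axis:

    D(m, n) = (t_m − s_n)²

and multi-axis distance matrices are summed element-wise
(e.g. D_GYGZ = D_GY + D_GZ).  An accumulated cost matrix is built
bottom-to-top by dynamic programming:

    C(0, n) = D(0, n)
    C(m, 0) = Σ_{i≤m} D(i, 0)
    C(m, n) = min{C(m−1, n−1), C(m−1, n), C(m, n−1)} + D(m, n)

Its top row is the **distance function** Δ(n) = C(M−1, n): the minimal
cost of warping the whole template onto a subsequence of *S* ending at
sample *n*.  Local minima of Δ below a threshold **τ** are stride-end
candidates; backtracking through C recovers each warping path and
hence the stride start.  Candidates are kept if their duration lies
strictly inside (250, 2000) ms and they overlap previously accepted
(cheaper) candidates by less than 100 ms.  τ regulates sensitivity:
the higher τ, the more minima qualify, the more strides (and
eventually non-strides) are detected.

The baseline detects the positive mid-swing peak on the sagittal
gyroscope axis GZ (> 150 °/s, ≥ 250 ms apart, highest peak wins) —
it finds virtually every stride but also fires on stair climbing.

Detections are scored against labels (borders within ±100 ms, one
label per detection) with precision, recall and their harmonic mean
(F-measure); τ is tuned by a grid sweep (5 … 130, step 5) under
leave-one-subject-out cross-validation.

## Worked example

```python
import stridedtw as st

# a free-walk-style recording: 20 strides plus a stair-climbing block
spec = st.WalkSpec(
    n_strides=20, seed=7,
    confounders=(st.ConfounderBlock("stairs", 10000.0, 200.0),),
)
signal, labels = st.generate_walk(spec)

template = st.normalize_template(st.canonical_template())
config = st.SegmentationConfig(tau=5.0, axes=("GY", "GZ"))
segments = st.segment_strides(st.normalize_signal(signal), template, config)

counts = st.match_strides(segments, labels, signal.fs)
metrics = st.compute_metrics(counts)
print(f"strides detected: {len(segments)} / {len(labels)} labeled")
print(f"first stride:     samples {segments[0].start}-{segments[0].end}, "
      f"cost {segments[0].cost:.3f}")
print(f"msDTW:         precision {metrics.precision:.2f}  recall {metrics.recall:.2f}  "
      f"F-measure {metrics.f_measure:.2f}")

peaks = st.detect_swing_peaks(signal.axis("GZ"), signal.fs)
pm = st.compute_metrics(st.match_peaks(peaks, labels))
print(f"peak baseline: precision {pm.precision:.2f}  recall {pm.recall:.2f}  "
      f"F-measure {pm.f_measure:.2f}")
```

prints

```
strides detected: 20 / 20 labeled
first stride:     samples 1127-1227, cost 0.054
msDTW:         precision 1.00  recall 1.00  F-measure 1.00
peak baseline: precision 0.65  recall 1.00  F-measure 0.78
```

All 20 strides are recovered with their borders, and the stair block
contributes nothing: its GZ bursts lack the negative border troughs of
a true stride, so their warping cost stays above τ.  The peak baseline
finds every stride too (recall 1.00) but marks eleven stair bursts as
strides, which is exactly the failure mode template matching removes.

The same pipeline is available from the shell:

```
stridedtw simulate --n-strides 20 --seed 7 --stairs-ms 10000 \
    --out-signal walk.csv --out-labels labels.csv
stridedtw template --signal walk.csv --labels labels.csv --out template.csv
stridedtw segment  --signal walk.csv --template template.csv \
    --tau 5 --axes GYGZ --out segments.csv
stridedtw evaluate --detections segments.csv --labels labels.csv --out scores.txt
```

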