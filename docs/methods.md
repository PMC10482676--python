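# Methods

This note documents the models and numerical procedures behind
`voltphys`: what the synthetic generator emulates, how each detection and
classification stage works, which parameters matter, and where design
choices were genuinely open.

## Signal model and sign convention

Soma-targeted Voltron fluorescence *decreases* with depolarization.  All
traces inside the package are already reversed (depolarization-positive);
only movie rendering and trace extraction deal with raw polarity.  A sweep
consists of a pre-stimulus baseline (default 0.5 s), a 20 Hz blue-light
pulse train of 1 s ("Op"), and a post period (default 1 s), sampled at
600 Hz.  At that frame rate an optical action potential (o-AP) spans 3–4
frames, which bounds both the detector's template and its half-width
filter.

## The synthetic generator

`voltphys.synthgen` is first-class, tested code: it defines the study
conditions every downstream stage is validated against.

* **o-AP kernel** — a biexponential rise/decay resampled to 3 frames
  (`[0.45, 1, 0.35]`, configurable to 4).  Amplitudes are in arbitrary dF
  units scaled so that the default noise SD of 1 makes amplitude 5 equal
  SNR 5; the conventional ~2–3 mV optical detection floor then corresponds
  to ~2 noise SDs.
* **PSP kernel** — an alpha function with τ = 8 ms, so consecutive
  responses in a 20 Hz train decay essentially to baseline between pulses
  (inter-pulse interval 50 ms).  Excitatory PSPs are positive, inhibitory
  negative; paired-pulse archetypes scale successive amplitudes by a
  constant ratio per pulse (facilitating 1.15, depressing 0.8).
* **Bursts** — a smooth (Hann) depolarized envelope of amplitude 3
  carrying 5 spikes at ~80 Hz; the rhythmic archetype repeats them at
  3.5 Hz, matching the rhythmic-bursting phenotype.
* **Stimulation artifacts** — single-frame negative-going (reversed
  polarity) deflections locked to each pulse onset, amplitude comparable
  to an o-AP.  Enabled by default.
* **Bleaching** — multiplicative monoexponential decay on the positive
  DC fluorescence level; disabled unless a time constant is given.
* **Timing** — events are quantized to the frame clock (kernels injected
  at integer frames with fixed shape).  This keeps the rate-resolution
  benchmark a pure question of frame-rate separation rather than
  conflating it with sub-frame amplitude sampling loss.
* **The "switch" archetype** alternates excitation-dominated and
  inhibition-dominated sweeps by sweep parity, emulating converging E/I
  inputs.

The generator does **not** model motion, hemodynamic contamination,
correlated (pink) noise, sub-frame event phase, or optical crosstalk
between ROIs beyond a Gaussian PSF.  Tests passing on these conditions
show the algorithms are correct under the stated signal model, not that
the thresholds are optimal for any particular preparation.

## Event detection

All thresholds are in units of the noise SD, estimated robustly: the
level is the median of the pre-stimulus baseline of the residual, and the
spread is 1.4826 × the median of negative deviations below that level
over the *whole* residual.  Depolarizing events only push the residual
up, so the negative side stays noise-dominated even under dense trains;
using the whole trace avoids the ±7 % sampling jitter a 300-frame
baseline segment alone would impose on the threshold.

1. **Artifact removal** — inside a ≤2-frame window at each pulse onset,
   samples dipping below the pre-pulse level by more than 3 SDs (with an
   absolute floor of 5 % of the local excursion range, so exact-zero noise
   does not flag flat samples) are replaced by linear interpolation.  Wide
   negative deflections (IPSPs) and transients away from pulses are never
   touched; the operation is idempotent.
2. **o-AP detection** — the residual (trace − o-Sub) is cross-correlated
   with the unit-norm o-AP template (matched filter, gain ‖k‖ ≈ 1.15);
   local maxima exceeding `k_mad` SDs above the baseline level, at least
   2 frames apart, are events.  Amplitude is read from the raw residual,
   half-width at half amplitude with linear sub-frame interpolation.
   Peaks wider than 6 ms are rejected: an o-AP spans 3–4 frames, so wide
   bumps are sub-threshold fluctuations (this also makes noise-free
   detection exact, where the floor is otherwise scale-free).
   `k_mad` defaults to **3.5**.  The choice follows from the detection
   budget: an SNR-5 spike yields a ~5.7 SD filtered peak with ~1.15 SD
   spread, so a 4 SD threshold recovers only ~94 % of spikes — below the
   95 % recovery the 125 Hz resolution claim requires — while 3.5 SD
   yields ~98 % at a false-positive cost of roughly one event per
   thousand frames.
3. **Iterative masking** — detection runs once against a spike-robust
   rolling 10th-percentile envelope (threshold relaxed by 1 SD; used only
   to seed the spike mask), then twice against the moving-average o-Sub
   recomputed with the union of all masks.  A missed spike would
   otherwise inflate the envelope under itself and suppress its own
   detection — the failure mode that caps naive two-pass schemes near
   90 % recovery at high rates.
4. **o-Sub** — centered moving average (default 25 frames ≈ 42 ms) after
   masking detected spikes ±1 frame and interpolating; a window spanning
   the trace returns the global mean.
5. **PSP detection** — per pulse, the AP-masked, 3-frame-smoothed trace is
   referenced to its value just before the pulse; the extremum of the
   deflection within the inter-pulse window is the PSP, polarity by sign,
   with events at or below `min_amp` (default 2 SDs) discarded.
6. **Burst detection** — candidates are stretches where o-Sub exceeds its
   *local slow level* (a rolling median over ~8 smoothing windows) by
   `depol_k` (default 2) SDs of the detrended envelope — the envelope's
   own noise scale, not the raw residual's, since 25-frame smoothing
   shrinks the fluctuation ~5-fold.  Local detrending stops a sustained
   PSP-train elevation from chaining separate burst envelopes into one
   candidate.  Gaps under two windows are merged; an interval qualifies
   iff it holds ≥ `min_aps` (2) spikes and its rate is ≥ `rate_mult` (2)
   times the whole-sweep rate.  Bursts longer than the detrending window
   (~330 ms at defaults) would be attenuated — the burst concept here is a
   transient episode, not a sustained state change.
7. **Compound decomposition** — difference of moving averages of two
   pharmacological conditions, recovering e.g. a disynaptic inhibitory
   component as (compound) − (isolated excitation).

## Features

Thirty named parameters are computed per sweep over the canonical
segments (Baseline, Op halves and 250 ms quarters, Post halves) and
averaged across a ROI's sweeps; sweeps where a ratio is undefined (zero
denominator) contribute NaN and are excluded from that average.  Two
departures from plain averaging: the total baseline spike count ("AP
num") *sums* over sweeps, and the bimodality pair is computed on o-AP
peak times pooled across sweeps.  Bursts are attributed to a segment by
overlap, and segment burst lengths measure the overlapping portion.

**Sarle's bimodality coefficient** is (skewness² + 1)/kurtosis with
population moments and non-excess kurtosis, the form that calibrates to
5/9 for the uniform distribution (variance 1/12, kurtosis 9/5).  A
variant omitting the "+1" is available behind a flag for comparison; it
evaluates to 0 for every symmetric distribution and cannot reproduce the
5/9 calibration, so it is not the default.  The binary flag is the
indicator coefficient > 5/9.  Peak *times* (not amplitudes) feed the
coefficient, since the phenotypes it separates are temporal (on-Op versus
rebound firing).

The clustering feature set holds 29 of the 30 parameters: the binary
bimodality flag is a deterministic threshold of the coefficient and is
stored but excluded from clustering.

## Clustering and classification

Because the parameters mix counts, rates, ratios and milliseconds,
columns are z-scored before Ward/Euclidean agglomeration; NaNs are
median-imputed per column at this step only (stored tables keep NaN), and
zero-variance columns are dropped with a warning.  The automatic cutoff
cuts at the midpoint of the largest gap between consecutive merge heights
— the corner where the cluster-count-versus-cutoff staircase enters its
longest plateau, i.e. the sharpest slope change in a scale-free sense.
(A fixed-grid second difference of the same curve lands in the dense
early-merge region of any large tree and was discarded for that reason.)

Cluster centroids are member means in standardized space.  The consensus
classifier ranks a query against all centroids by Euclidean distance and
by Pearson correlation, intersects the two top-3 lists, and assigns the
smallest rank sum, breaking ties by distance rank and then raw distance;
disjoint lists leave the neuron unassigned.  Correlation is invariant to
affine transforms of the query, distance is not — the two rankings carry
complementary information, which is the point of requiring their
consensus.  Cluster-load analysis classifies an external population and
reports per-cluster fractions plus the unassigned fraction (summing
to 1).

## Spatial statistics

Coordinates live in a micrometre frame built from the FOV tiling
(200 × 350 µm² fields, X/Y from tile index and pixel centroid, Z from the
section's anterior–posterior position).  Voxel criterion maps use 200 µm
cubes (the mapped face is 200 × 200 µm²; depth is a configurable choice)
and report the percentage of contained neurons meeting a boolean
criterion — empty voxels are undefined and excluded, not 0 %.  Density
cores maximize the 300 µm-radius neighbor count, ties to the lowest
index.

The AMD shuffle test permutes the full label vector (default 1,000
shuffles) and recomputes the mean minimal ref→target distance per
shuffle; the per-cell metric contrasts each reference cell's minimal
distance with the scalar null mean, and its s.e.m. is bootstrapped
(1,000 resamples) over reference cells.  Self-distances are excluded when
reference and target coincide; a singleton same-cluster reference is
flagged and yields NaN.  An empirical two-sided p-value comes from the
shuffle rank.  Feature/space coherence correlates the upper triangles of
the k × k feature-centroid and spatial-centroid distance matrices
(Pearson), requiring k ≥ 3.

## Multi-recording comparison

ROIs are paired across recordings by mutual nearest centroids within a
shift budget.  Relative change is (after − before)/before with the
before-recording as reference; status is *increased* above +25 %,
*decreased* below −25 %, otherwise *unchanged* — growth from an exactly
silent baseline counts as increased, two silent recordings as unchanged.
The cutoff applies to the cross-sweep mean; per-sweep values are emitted
alongside ("total burst length" is the per-sweep sum of burst durations).

## Benchmark problem sizes

The test suite runs entirely on synthetic data: sweeps of 1,500 frames,
feature blobs of ≤200 rows, point sets of ≤400 neurons, shuffle tests at
300–1,000 permutations.  The rate-resolution benchmark in
`scripts/acceptance.py` uses 10 s traces with ten repeats per rate
(50–150 Hz, ~50,000 spikes per run); its reduced in-suite version uses
4 s traces and three repeats at 100 and 125 Hz.

## Known limitations

* Noise is white Gaussian (rendering optionally Poisson); correlated
  noise or motion would loosen the detection guarantees.
* The bleach fit assumes a monoexponential trend on a positive DC level;
  biexponential bleaching is fitted only by its dominant component.
* PSP amplitudes of overlapping responses are referenced to the pre-pulse
  level, so strong temporal summation biases amplitudes (not counts).
* The concentric somatic check compares ring amplitudes at given AP
  frames; it assumes the neuropil background is not itself spiking
  coherently at those frames.
* Coordinate mapping is a rigid tiling: no atlas registration, slice
  deformation, or hemispheric mirroring.
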