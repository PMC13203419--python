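# Methods

`hdfmap` localizes spatiotemporally stable high-dominant-frequency (HDF)
areas of the left atrium from sequentially mapped bipolar electrograms.
This note documents the model assumptions, the parameters that matter,
what the synthetic data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Signal model and per-point spectral analysis

During atrial fibrillation the local activation rate of atrial tissue is
summarized by the dominant frequency (DF): the largest spectral peak of
the preprocessed electrogram inside the physiological 4–10 Hz band. Each
mapping coordinate point (position sampled at 40 Hz, electrograms at
1000 Hz) is characterized by the 2-s signal window centered on its
acquisition time:

1. **Quality gating.** Windows outside a fibrillatory period of the
   reference (coronary-sinus-like) channel, with peak amplitude below
   0.2 mV (poor contact) or above 16 mV (artifact), or with more than
   half of their spectral energy within ±1 Hz of the power-line
   frequency, are discarded. The "excessive power-line energy" fraction
   (default 0.5) and the AF cycle-length criterion (running median
   < 250 ms over 9 cycles, minimum 5 s span) are free parameters of this
   implementation, exposed in `QualityConfig`.
2. **Botteron filtering.** 40–250 Hz bandpass, rectification, 20 Hz
   low-pass. This converts sharp biphasic deflections into a smooth
   activation-rate envelope. Both stages are 4th-order Butterworth
   filters applied forward–backward (zero phase), so activation times
   are not shifted.
3. **Welch spectrum.** Hamming-windowed 1-s segments with 50% overlap,
   zero-padded so the grid step is 0.05 Hz. The 0.05 Hz step is finer
   than the window's intrinsic 0.5–1 Hz resolution; zero-padding is the
   standard interpolating reading of that requirement. Segment means are
   removed (`detrend='constant'`) so the rectified envelope's DC offset
   does not dominate the 0–20 Hz band that normalizes the OI.
4. **DF pick.** Grid argmax restricted to [4, 10] Hz; exact ties resolve
   to the lowest frequency, which avoids harmonic capture.
5. **Organization Index.** OI = (power within ±0.375 Hz of the DF and of
   each harmonic peak ≤ 20 Hz) / (total power in 0–20 Hz). Bands are
   unioned before summation, so overlapping windows are never double
   counted, and the union is clipped to the denominator range — this
   guarantees OI ∈ [0, 1]. Harmonic band centers are the local spectral
   maximum within ±0.5 Hz of each integer multiple of the DF (ties:
   highest power, then closest to the exact multiple, then lowest
   frequency); when no local maximum exists the exact multiple is used.
   Points with OI < 0.2 are rejected as insufficiently significant.

## Spatial aggregation

Coordinate points are pooled into 2 mm cubic voxels over a 100 mm
bounding cube (half-open cells, indices = floor((p − origin)/size)). The
cube's size is fixed; its placement is not dictated by the data format,
so by default the cube is centered on the coordinate cloud's bounding
box, with a fixed-origin option for reproducible comparisons (the
synthetic datasets use origin (0,0,0)).

Within each voxel, points are **sparsely sampled in time**: points are
sorted by mapping time, a balanced binary search tree is built by
recursive midpoint splitting (lower middle on even splits), and a
breadth-first traversal (left child before right) collects node ranks
until the queue holds 31 points. This keeps an approximately
equally spaced temporal subset spanning the voxel's full time range
while capping the number of spectral evaluations per voxel. DF/OI are
computed **only** for the sampled subset — reducing computation is the
purpose of the sampling.

The voxel's DF is the **trimmed mean** of its valid per-point DFs:
k = ⌊αn⌋ smallest and largest values are discarded and the rest
averaged. α is not fixed by the method's description; the default is
α = 0.2 (one value per five trimmed from each end), which removes
occasional OI-passing outliers while keeping most of the sequence;
⌊αn⌋ with α < 0.5 guarantees a nonempty core. Voxels with fewer than
`min_points = 3` valid DFs are excluded: a trimmed mean over one or two
values is not a stability statistic. Bookkeeping distinguishes visited,
effective (≥ min_points valid DFs) and saturated (≥ 31 points) voxels.

## Neighborhood smoothing

Each voxel's DF is replaced by the arithmetic mean of its own value and
its 10 nearest neighboring voxels' values (Euclidean distance between
centroids). All averages are computed from the pre-smoothing snapshot —
"update" is read as simultaneous, not sequential, which makes the result
independent of traversal order. The neighbor search uses a kd-tree
(scipy `cKDTree`) with deterministic tie-breaking at the k-th distance
by lexicographic voxel index; centroid coordinates on the 2 mm lattice
are exactly representable, so squared-distance ties are resolved
exactly. The smoothed field is a convex combination of raw values: the
global [min, max] never expands, and in practice variance decreases.
One smoothing pass is applied.

## Personalized HDF threshold

Because the intrinsic DF varies across patients, the HDF area is defined
against the subject's own distribution: threshold = mean + 1 × SD of the
smoothed voxel DFs, and voxels **strictly above** it are labeled 1.
Sample SD (ddof = 1) is the default; population SD is available.
Equality labels 0, so a constant model yields an empty HDF set. No
connected-component post-processing is applied — voxels are labeled
individually.

## OI threshold calibration

Given segments labeled positive (significant DF) or negative, thresholds
0, 0.05, …, 1.0 are scored with precision, recall and F1; OI equal to
the threshold counts as predicted positive (consistent with "less than
the threshold is filtered out"). 0/0 ratios are defined as 0. The argmax
resolves ties to the lowest threshold. The clinically labeled corpus
used to justify 0.2 is proprietary; the module accepts any labeled
table, and tests supply synthetic mixtures with a known boundary.

## Synthetic data generator

The generator stands in for proprietary clinical recordings and defines
the study conditions of the test suite:

- **Surface:** an axis-aligned ellipsoid shell (radii 42/36/30 mm)
  inscribed in the 100 mm cube — real atrial anatomy is out of scope.
- **DF field:** base level + optional linear gradient + Gaussian focal
  patches (amplitude = peak − base, SD = patch radius), clipped to
  [4, 10] Hz. The default study field is two-component: uniform 6 Hz
  base plus one +2.5 Hz patch of 8 mm radius on the shell. A smooth
  gradient is deliberately absent from the default: under a mean + 1 SD
  rule, a shallow gradient places the threshold inside its own upper
  tail, where a 0.1 Hz estimation error moves the truth/estimate
  boundary by ~10 mm and the overlap score measures threshold
  ill-conditioning rather than localization. A gradient + patch preset
  (`gradient_field`) is provided for demonstrations.
- **Trajectory:** independent per-channel random walks in surface-angle
  space at 40 Hz with dwell spans (1–3 s of near-zero drift, probability
  0.4 per free second) and abrupt repositionings (mean every 7 s),
  producing uneven density and long per-voxel time spans; ±0.3 mm radial
  jitter. The clinical density distribution is unquantified, so these
  dwell parameters are free knobs with physiologically plausible scales,
  not calibrated values.
- **Electrograms:** biphasic deflections (two opposed half-sines, 20 ms,
  ~1 mV) placed at activation times whose instantaneous cycle length is
  1/DF(position) with multiplicative Gaussian jitter (SD 5%, truncated
  at ±3 SD); additive Gaussian noise (0.05 mV), dropout spans (0.5–2 s
  scaled below the 0.2 mV floor, 1/min), >16 mV artifacts (2/min) and a
  50 Hz power-line sinusoid (0.05 mV; 50 Hz default, configurable to
  60). A clean reference train (160 ms cycle length; 600 ms during an
  optional "sinus" prefix) is appended for AF gating.
- **Ground truth:** per-point field values and the HDF voxel mask
  obtained by applying the same mean + 1 SD rule to the noiseless field
  at visited-voxel centroids.

What the generator does **not** emulate: fibrillatory conduction and
wavefront fusion, realistic anatomy, spatial catheter-spline geometry,
far-field ventricular components, and the clinical mapping-density
distribution. Passing tests therefore demonstrate that the pipeline
recovers a known rate field from pulse-train-like signals under the
modeled corruptions — not clinical accuracy.

## Problem sizes and evaluation

Test and acceptance runs use 60 s acquisitions with 15 mapping channels
(36 000 coordinate points) — a deliberate scale-down of the ~30 min
clinical sessions that keeps the voxel statistics meaningful (hundreds
of effective voxels, tens of saturated ones). End-to-end accuracy is
scored on the voxels where the model makes a decision: the ground-truth
mask restricted to effective voxels is compared with the labeled set via
Dice and recall. DF-estimator accuracy is measured on standalone clean
2-s windows with rates drawn uniformly from [4.5, 9.5] Hz. The shell
coverage floor for the default 60-s trajectory is 10% of on-shell
voxels; a full-length clinical acquisition would cover far more.

## Known limitations

- The per-point DF assumes local rate stationarity within the 2-s
  window; the simulator's dwells make this mostly true, and drifting
  windows blur like an extra smoothing term.
- The mean + 1 SD rule is sensitive to the DF distribution's shape; on
  near-uniform fields the HDF boundary is intrinsically unstable (see
  the gradient discussion above).
- The BST/BFS sparse sampler is rank-based; with 31 = 2^5 − 1 it takes
  complete tree levels, giving near-uniform coverage, but other queue
  lengths leave the deepest level partially covered on the left side.
- AF gating requires a reference channel; without one the pipeline
  analyzes the whole recording and relies on the window-level filters.
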