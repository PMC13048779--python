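# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `edagraph`. It is the authoritative record of the
design decisions that were genuinely open; the README gives the short
overview.

## Signal model and preprocessing

A recording is a set of uniformly sampled channels (`TimeSeries`: values,
rate, units) plus continuous arousal/valence annotation traces on a 0.5–9.5
rating scale. All filtering is zero-phase (forward–backward second-order
sections): the phase response of a causal filter would shift
skin-conductance response (SCR) peaks by hundreds of milliseconds, which
matters when windows are labeled at their center sample.

Per-modality conditioning defaults:

| channel | pipeline |
|---|---|
| EDA (external hardware) | resample to 20 Hz → 1 Hz low-pass (order 3) → 21-sample running median → min–max scaling |
| ECG | 0.5–40 Hz band-pass, order 3 |
| PPG | 0.7–3.5 Hz band-pass, order 3 (42–210 bpm cardiac band) |
| EMG | 20–450 Hz band-pass → 50 Hz notch (configurable for 60 Hz mains) → 100 ms RMS envelope |
| RESP | 0.1–0.5 Hz band-pass, order 2 → 0.05 Hz high-pass → amplitude normalization |
| SKT | 0.1 Hz low-pass → linear detrend |

A nominal "20-sample" median window is promoted to 21 samples so the kernel
is symmetric about each sample; running medians with even windows are
ambiguous. Resampling uses polyphase filtering with line-extension padding
(anti-aliased; constants and ramps pass exactly).

**Windowing.** Default 60 s windows with 50% overlap; windows start at
multiples of the hop and are kept only while fully inside the record. Each
window's affect label is the annotation value at the window center; the
per-window mean is available as an option (`label_mode="mean"`). The two
conventions differ only when the annotation moves within a window, and the
center convention is the default because it anchors the label to a single
well-defined time point.

## Tonic/phasic decomposition and traditional features

The decomposition is additive by construction: the tonic component is the
least-squares line of the window plus the 0.05 Hz low-pass (order 4,
zero-phase) of the residual, and the phasic component is the exact
remainder, so `tonic + phasic == eda` to machine precision. Subtracting the
line before filtering removes the finite-window edge bias that would
otherwise distort the recovered tonic slope (a pure ramp now round-trips to
its slope within 1e-9 μS/s). Convex-optimization decompositions are out of
scope; the low-pass split is deterministic, fast and satisfies the additive
identity exactly.

Non-specific SCRs are local maxima of the phasic trace with at least 1 s
separation whose rise from the onset level reaches the amplitude threshold
(default 0.05 μS, matching the quantization step; configurable). The onset
level is the preceding trough **or the zero baseline, whichever is
higher** — low-pass tonic extraction leaves small negative undershoots
around large SCRs, and measuring rebounds from their undershot trough would
otherwise inflate their apparent amplitude and double-count events.

TVSymp (time-varying sympathetic tone) is the analytic-signal envelope of
the 0.08–0.24 Hz band of the window — the sympathetic band convention of
the EDA spectral literature; the band edges are parameters, not facts about
the construct. Summaries: mean, SD, max, min, and energy
(`Σ envelope² / fs`, μS²·s). Spectral band powers integrate a periodogram
of the mean-removed window over LF = 0.045–0.15 Hz and HF = 0.15–0.25 Hz
(configurable); a zero HF power reports the LF/HF ratio as `+inf` rather
than raising.

The traditional roster is frozen at 19 names (6 phasic incl. the SCR count,
5 tonic incl. the OLS slope in μS/s, 5 TVSymp, 3 spectral) and asserted in
code.

## The EDA-graph

Quantization maps each sample to `Q · round(x/Q)` with `Q = 0.05 μS`;
half-step ties round away from zero (platform-independent, unlike bankers'
rounding), with a 1e-9 relative epsilon guarding binary representation of
exact half-steps. Nodes are identified internally by their integer level
index, making node identity exact in floating point.

Candidate edges come from temporal co-occurrence only: consecutive samples
on distinct levels register their unordered level pair; same-level
successions are revisits of one node, never self-loops. Each node then
keeps its k nearest candidates by conductance distance; candidates tied
with the k-th distance are **all kept**, which makes the selection
deterministic and independent of sample order. The edge set is the
undirected union of the per-node selections, so a node's final degree can
exceed k — this is a property of mutual-kNN-union constructions, not a
defect, and is covered by tests. `k` defaults to `round(fs)` (one second of
temporal coverage): 8 for 8 Hz processed signals, 20 for the 20 Hz external
convention.

Weights are `w_ij = 1/D_ij ≤ 1/Q`; the adjacency is symmetric with zero
diagonal, and `L = D − A` is the weighted combinatorial Laplacian (PSD,
zero row sums, one zero eigenvalue per connected component). A constant
window yields a valid 1-node, 0-edge graph rather than an error.

## Graph features (66-name manifest)

The manifest is the single source of truth for roster order and records
per-feature category and whether weights enter the computation
(`manifest_json()` exports it). Conventions:

- **Counting metrics** (triangles, transitivity, maximal cliques, degree
  centrality, assortativity) use the unweighted skeleton.
- **Distance metrics** (closeness, betweenness, harmonic, eccentricity,
  diameter/radius/periphery) use the conductance difference `D_ij = 1/w_ij`
  as edge length.
- **Spectral and flow metrics** use the weighted adjacency; edge weights
  act as affinities/conductances.
- **Disconnected graphs**: eigenvector centrality, eccentricities and
  current-flow metrics are computed on the largest connected component
  (ties broken by size, then smallest minimum node, deterministically);
  off-component nodes contribute the 0 sentinel. "Component eccentricity"
  is the maximum eccentricity within that component.
- **Degenerate graphs** (single node or no edges) emit documented zero
  sentinels for every metric instead of raising, so any window maps to a
  full-length vector.

Eigenvector centrality is the principal eigenvector of the component's
weighted adjacency from a dense symmetric eigendecomposition, reported with
unit L2 norm and non-negative entries (the Perron root of a connected
non-negative matrix is simple, so this is well-defined); the "total" is the
sum over nodes. Iterative solvers were rejected because ARPACK is unreliable
for the 2–3-node components that quiet windows produce. Current-flow
(random-walk) betweenness and closeness follow the electrical-network
definitions; on 2-node components the standard normalization constant
`(n−1)(n−2)` vanishes and the unnormalized values are used (node
throughflow is 0 there regardless). Degree assortativity is undefined for
regular graphs (zero degree variance) and reports the 0 sentinel.

The Weisfeiler–Lehman signature starts from degree labels, applies h = 2
refinement iterations (rehashing each node's label with the sorted multiset
of neighbor labels), and reports the number of distinct final labels
divided by the node count — 1/n for vertex-transitive graphs, approaching 1
as local structure diversifies. It is a scalar structural-diversity summary
in the WL family, not a graph kernel between window pairs.

Every centrality, spectral and flow metric is checked against an
independent brute-force implementation (Floyd–Warshall, exhaustive path
enumeration, shifted power iteration, Laplacian pseudoinverse flows, subset
enumeration) on seeded random graphs of ≤ 8 nodes; the test graphs use
dyadic edge weights so shortest-path sums are exact in binary and
equal-length-path tie detection is order-independent.

## Multimodal baseline (53-name manifest)

R peaks come from the classic energy pipeline (derivative → squaring →
150 ms moving-window integration → adaptive threshold → refinement to the
local ECG maximum). RR intervals outside 277–1500 ms (40–216 bpm) are
treated as artifacts: short intervals are dropped as spurious detections,
long gaps are filled by cubic-spline interpolation of the RR series. The
same plausibility bounds are applied to PPG inter-beat intervals; PPG beats
are detected from the squared negative second derivative (upstroke
curvature) against a time-adaptive threshold (2 s moving average), refined
to the systolic peak.

HRV: instantaneous-heart-rate statistics, SDNN/RMSSD (ms), pNN50 (%), and
VLF/LF/HF band powers (< 0.04 / 0.04–0.15 / 0.15–0.4 Hz) of the RR
tachogram resampled at 4 Hz, detrended, Welch-estimated; the
frequency-domain block requires a ≥ 60 s beat span and reports NaN below
it. PTT is the delay from each R peak to the next PPG beat within 600 ms
(unmatched beats skipped), summarized by mean/SD/min/max and the OLS slope
in ms/s. Respiration rate comes from peak intervals, the
inspiration/expiration ratio from zero crossings of the centered signal.
EMG amplitude descriptors (RMS, MAV, SSI, waveform length) use the RMS
envelope when one is supplied; spectral descriptors (median/mean frequency)
and distribution shape (kurtosis, skewness) always use the band-passed
pre-envelope signal. Missing or degenerate channels yield NaN markers so
the 53-column table stays rectangular.

## Evaluation protocol

Outer loop: leave-one-subject-out. Inner loop: subject-grouped 5-fold grid
search minimizing the mean inner-validation RMSE averaged over arousal and
valence; the inner scaler is refit on each inner-training split. Feature
standardization (zero mean, unit variance) is estimated from the outer
training rows only and applied to the held-out subject with those frozen
statistics. Nothing derived from the held-out subject can reach the model:
a metamorphic test corrupts the held-out rows arbitrarily and asserts
bit-identical coefficients and scaler statistics.

Two robustness guards sit inside the standardization contract, both
computed from training rows only:

- training features whose SD falls below `1e-10 · (1 + |mean|)` are dropped
  (numerically constant columns otherwise produce float-noise SDs of order
  1e-16 and astronomically scaled test values);
- standardized values are winsorized at |z| ≤ 5 (default, configurable).
  Several graph metrics are heavy-tailed: a quiet low-arousal window yields
  a tiny 3-node graph whose per-node flow and closeness scores sit tens of
  training SDs outside the cohort distribution, and an unclipped linear
  model extrapolates wildly on such windows.

Model families: ridge / lasso / elastic net and three gradient-boosted tree
variants (LightGBM, histogram gradient boosting, classic gradient
boosting), with compact default grids spanning the usual search ranges
(ridge/lasso alpha 1e-4…1e2, tree learning rates 1e-3…1e-1, etc.).

Metrics: RMSE, MAE, R², and a balanced RMSE defined as the mean of per-bin
RMSEs over 9 equal-width label bins spanning [0.5, 9.5] — it weights
sparsely populated label regions equally with dense ones; plain RMSE is
always reported alongside and is what cross-model comparisons use.

**Permutation importance** implements
`I_f = (1/N) Σ_i (e_i^(p) − e^(b))` with `e^(b)` the unpermuted held-out
RMSE and `e_i^(p)` the RMSE after shuffling only column f in repeat i
(N = 100 by default), computed within each LOSO fold and averaged across
folds; a [0, 1]-normalized copy (negatives clipped, divided by the maximum)
is emitted next to the raw values. Impurity importances (MDI) are attached
where the model exposes them and marked not-applicable otherwise, never
zero-filled. **Ablation** retrains from scratch within every fold with the
target feature removed and reports the mean per-fold
`%ΔRMSE = 100·(RMSE_without − RMSE_with)/RMSE_with` with a percentile
bootstrap CI (1000 resamples of the fold-level values). **VIF** is
`1/(1 − R²)` of a feature regressed with intercept on the rest; exact
collinearity reports `+inf`.

**Quadrant statistics.** Overlapping windows are autocorrelated, so
inference runs at the subject level: the per-subject median of each feature
within each affective quadrant (LALV/LAHV/HALV/HAHV/Neutral; θ = 5 split,
Neutral = both dimensions within (4, 6), checked first) gives one
observation per subject per quadrant; quadrant pairs are compared across
subjects with two-sided Mann–Whitney U tests, and Holm–Bonferroni is
applied over the full feature × pair family at α = 0.005. The default pair
family is all 10 unordered quadrant pairs; a 4-pair each-versus-Neutral
family is a config switch. Shapiro–Wilk normality p-values are reported per
feature as a screen, not a gate. Pairs with an empty quadrant are marked
untestable rather than assigned a p-value.

## Continuous-to-class mapping

Fixed midpoint threshold θ = 5.0, boundary semantics exactly as printed
(≥ θ vs < θ). Three schemes: three-way emotion (negative iff V < θ;
positive iff A < θ and V ≥ θ; mixed otherwise), five-state quadrant mapping
on the 1–9 scale (inputs on 0.5–9.5 are first affinely rescaled,
`v' = 1 + (v − 0.5)·8/9`, midpoints aligned; the Neutral band
|A−5| < 1 ∧ |V−5| < 1 is evaluated **before** the quadrant split, a
precedence the rules themselves leave open), and binary stress (Stress iff
A ≥ θ). Totality — every in-range (A, V) receives exactly one class per
scheme — is verified on a 0.1-resolution grid. A θ-sensitivity probe remaps
all labels at θ ± 0.5 and reports the absolute accuracy change.

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, with an
explicit, recorded affect coupling:

- annotation traces: piecewise-constant quadrant targets (LALV (2.5, 2.5)
  … HAHV (7.5, 7.5), Neutral (5, 5)) plus AR(1) jitter (φ = 0.95,
  stationary SD 0.25), clipped to [0.5, 9.5];
- EDA: tonic level `2.0 + 0.08·(valence − 5)` μS, SCR onsets from an
  inhomogeneous Poisson process with intensity `0.02·arousal(t)` per
  second (thinning), amplitudes `0.15 + 0.06·arousal` μS (±20% jitter),
  bi-exponential SCR kernel `(1 − e^{−t/0.75})·e^{−t/4}` normalized to unit
  peak (rise 0.75 s, recovery 4 s — the standard psychophysiological
  shape), additive Gaussian noise SD 0.01 μS;
- companion channels: spike-train ECG, raised-cosine PPG delayed by the
  pulse transit time, sinusoidal respiration, linear-drift temperature,
  burst-modulated EMG carrier. These are shape stand-ins for detector and
  feature tests, not physiological simulations;
- every generator is a pure function of its arguments including the seed.

Default cohort for recovery experiments: 10 subjects × 330 s at 8 Hz
(10 windows each after 60 s/50% windowing), cycling through the four
non-neutral quadrants. Passing tests on these cohorts demonstrates that the
pipeline recovers a known coupling and respects its contracts; it does not
certify error levels on real recordings, which add sensor artifacts,
motion, inter-subject diversity and annotation idiosyncrasies the generator
does not model.

## Problem sizes used by the verification scripts

The acceptance script and test suite run at desk scale, chosen as the
smallest sizes at which each property is convincingly exercised: 200 random
graphs for oracle equivalence, 100 synthetic windows for construction
invariants, 20 replicate cohorts (10 subjects each) for the
coupling-recovery comparison against the shuffled-label null with a fixed
ridge penalty (α = 1; the comparison needs a fixed model, not a tuned one),
N = 100 permutation repeats, 1000 bootstrap resamples.

## Known limitations

- The tonic/phasic split is a linear filter decomposition; it does not
  deconvolve overlapping SCRs, and the SCR count undercounts bursts closer
  than the 1 s refractory separation.
- TVSymp band edges and the EDA LF/HF bands are conventions; reported
  values are comparable within a configuration only.
- The kNN-union construction makes node degree depend on co-occurrence
  richness; graphs from windows of very different activity levels differ in
  size, which is informative but makes several per-node summaries
  heavy-tailed (hence the winsorization above).
- Beat detection is tuned for clean or mildly noisy signals; heavily
  motion-contaminated ECG/PPG needs upstream artifact handling.
- EEG and video channels, deep-learning baselines, and event-related
  (stimulus-locked) SCR scoring are out of scope.
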