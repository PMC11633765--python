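# Methods

This note documents the model, the defaults and the design choices behind
`capdyn`, and what the synthetic validation does and does not establish.

## The analysis model

The pipeline treats the brain's resting activity as passing through
transient, recurring whole-brain states gated by the activity of a small
seed nucleus. Operationally a state (co-activation pattern, CAP) is a
cluster centroid over z-scored fMRI frames selected at moments of high seed
activation. The assumptions this encodes:

- Seed-related network events are *sparse* and *high-amplitude*: only the
  upper tail of the seed time course (default z > 0.84, the 80th percentile
  of a standard normal) carries state information; the rest of the scan is
  treated as background and never clustered.
- States are *discrete and recurring*: the same spatial patterns reappear
  across frames and subjects, so a reference clustering built from healthy
  controls is meaningful for patients. The reference population is the
  control group because patient activity is hypothesized to deviate from it.
- State dynamics are summarized by a *first-order* description: entries,
  dwell durations, occupancies, and the transition matrix
  `T[m, n] = P(state n at t+1 | state m at t)` over originally adjacent
  frame pairs. No higher-order temporal dependence is modeled.

## Pipeline stages and numerical choices

**Preprocessing** runs in a fixed order — nuisance regression, high-pass,
optional smoothing, scrubbing, z-scoring — and is exactly linear up to the
flagging steps, so reruns are bit-identical.

- Framewise displacement uses a 50 mm head radius to convert rotations to
  arc length (Power's convention); scrubbing threshold 0.5 mm. Censored
  frames are flagged, never deleted: the dynamics stage needs original
  temporal adjacency.
- The high-pass filter (cutoff 0.01 Hz) is a discrete-cosine-basis
  regression (components with frequency below the cutoff, plus the
  constant), fit on valid frames only. A projection was chosen over an IIR
  filter because it is exactly linear, has no transient, and cannot leak
  censored frames into valid ones. Stopband attenuation is measured as
  residual RMS amplitude; edge leakage of a non-commensurate tone
  concentrates in the first/last few frames.
- z-scoring uses valid frames with `ddof = 1`; zero-variance voxels are set
  to 0 and flagged rather than producing NaNs.
- The global-signal regressor (whole-mask mean course) is on by default and
  switchable, since its use is debated but materially improves data quality
  in this analysis family.
- Smoothing (optional) takes its FWHM in voxel units: the pipeline consumes
  already-normalized grids and makes no claims about mm geometry.

**Frame selection** thresholds the weighted-mean seed course, by default
after z-scoring the course itself over valid frames (whether thresholding
applies to the re-standardized course or the raw weighted mean of z-scored
voxels is underdetermined; both are implemented, the default is the former).
Probabilistic seed weights are used as-is rather than binarized, which
preserves atlas information for small nuclei. A `top_fraction` mode is
provided because the z-threshold and the nominal percentile coincide only
under normality; the realized count is always reported.

**Consensus clustering** subsamples 80% of the pooled reference frames 100
times per candidate K, k-means with one initialization each; consensus is
co-clustered count over co-sampled count, pairs never co-sampled are
excluded from PAC. PAC bounds are (0.1, 0.9). K is chosen by maximal
1 − PAC with ties broken toward smaller K — an automated, reproducible
stand-in for visual consensus-matrix inspection; the full PAC table and the
matrices are emitted for exactly that inspection. Euclidean k-means on
z-scored frames is monotonically related to spatial correlation for
standardized vectors.

**CAP construction**: maps are voxel-wise means of member frames, z-scored
across voxels (so display thresholds like ±1.04, the 15% tails of a
standard normal, apply); CAPs are indexed by descending member count, so
CAP 1 is always the most occupied. Each CAP stores its member-frame
correlation distribution; the 5th percentile of that distribution is the
assignment threshold. This distribution is the only correlation null
available per CAP at assignment time.

**Assignment** is deliberately asymmetric: reference (control) frames keep
their k-means labels; patient (or held-out) frames must clear the
threshold or remain UNASSIGNED. A symmetric re-assignment switch exists
for sensitivity analyses. Argmax ties break toward the lower CAP index.

**Dynamics — gap handling.** The central under-specification of this
analysis family is what a "transition" means when frames are missing. The
default (`strict`) counts only pairs adjacent in the original timeline with
CAP labels at both ends; censored, unselected and unassigned frames break
runs and contribute nothing. The alternative (`collapse`) splices assigned
frames across gaps. Strict is the default because "timepoint t to t+1"
reads as literal adjacency; collapse is reported side-by-side when asked.
Rows of T with zero observed pairs propagate as *missing*, never as zeros:
a zero would fabricate certainty about an unobserved row. Durations are
mean run length × TR in seconds; entries are raw run counts, with the
excluded-frame covariate carrying session-length correction downstream.

**Inference.** Each metric is compared by OLS `metric ~ group + covariates`
on complete cases (covariates: excluded frames, selected frames, age, sex,
medication, depression, state anxiety; near-collinear columns pruned with a
warning). Cohen's d uses covariate-residualized values with a pooled-SD
standardizer — the standardizer is not fixed by convention in this
literature, so it is stated here and in output headers, as is the sign
convention (patient − control). FDR families are kept separate: the K²
transition cells form one family, entries and durations each their own,
mirroring how these results are reported. The Mann–Whitney Z uses tie and
continuity corrections (the continuity-corrected extreme at n = 14/14 is
|Z| = 4.48); Welch's t from printed summaries uses the Welch–Satterthwaite
df. Seizure-count correlations use Spearman, because seizure counts are
heavily skewed count data.

## The synthetic generator

`capdyn.synth` emulates the study conditions: two groups of 14 subjects,
300 frames at TR = 1.3 s, three planted co-activation patterns, covariates
on the study's descriptive scales, and motion spikes injected as
instantaneous ±1 mm translation jumps (putting FD above 0.5 mm at exactly
the spiked frame) over a gentle random walk.

Key generator design points:

- The latent chain has an explicit quiescent **baseline** state in which the
  seed is silent, so frame selection has a real signal to find — the
  analysis only makes sense if high-seed frames are a minority.
- Patterns are smooth Gaussian blobs at mutually distant grid corners
  (pairwise spatial correlation < 0.5), **spatially zero-mean** (activation
  balanced by weak deactivation, as real CAPs mix both). The zero mean is
  load-bearing: a nonzero-mean pattern would put the latent state into the
  global-signal regressor, and global-signal regression would then remove
  the very seed signal the selection stage needs. Blob tails are zeroed at
  the seed voxels so every state carries an identical unit seed loading and
  selection is unbiased across states.
- The group difference is a persistence (diagonal) boost: control states
  stay with probability 0.50 and switch to each other state with 0.05;
  patient states stay with 0.60 and switch with 0.04 — i.e. higher
  persistence is expressed as uniformly reduced switching, preserving the
  exit-structure proportions. This matters because frame selection censors
  exits to the baseline: the observable diagonal is approximately
  `p_stay / (p_stay + cross-switching)`, so a boost taken purely from
  baseline returns would be almost invisible in the measured transition
  matrix. The +0.10 scale is a module choice; no empirical effect-size
  scale exists for it.
- Covariates are drawn independent of group by default (apart from the
  structurally patient-only medication flag), so the adjustment stage can
  be tested under a true null; a `covariate_confound` knob scales in the
  descriptive-table group separation for confounded scenarios. Seizure
  counts are negative-binomial (mean ≈ 6.6, SD ≈ 13), matching the heavy
  skew of such data.
- One integer seed fans out to per-subject substreams via
  `SeedSequence(seed, spawn_key=(group, subject))`: cohorts are
  byte-identical across runs and subjects are independent.

What the generator does **not** emulate: hemodynamic convolution,
physiological (cardiac/respiratory) noise, spatial autocorrelation of the
noise floor, scanner drift beyond polynomial trends, registration error,
or anatomically realistic geometry. Passing tests therefore demonstrate
the correctness and calibration of the *computation* under the assumed
state-switching model — not that real data satisfy that model.

## Validation problem sizes

The test suite exercises the estimator-consistency checks at 10,000-frame
chains (transition estimates within 0.02 of truth), K-selection recovery
on 20 replicates of 150 frames × 300 voxels, full-pipeline sign recovery
of the planted persistence boost on 20 replicate cohorts of 14 + 14
subjects on a 12×12×8 grid (group-level transition estimates pool raw
counts over subjects before normalizing), and type-I-error calibration of
the adjusted group test over 1,000 null replicates (rejection rate
0.05 ± 0.02). The acceptance script's stability scan uses 200 frames ×
500 voxels, K = 2..8, 100 subsamples — a scale at which a full scan
completes in seconds per replicate while leaving the planted structure
non-trivial to recover.

## Known limitations

- Automated K selection by max(1 − PAC) can differ from a human reading of
  the consensus matrices in borderline cases; the diagnostics are emitted
  so the human step remains possible.
- Frame selection followed by transition estimation biases diagonals upward
  (within-run pairs survive censoring preferentially) and distorts
  probabilities relative to the latent chain; group *contrasts* remain
  interpretable, absolute transition probabilities should be read with
  care.
- Per-subject transition rows with few observed pairs are noisy; rows with
  none are missing, which reduces the effective n of downstream tests.
- The Welch test from printed summary statistics inherits the rounding of
  those summaries (df reproducible to ~0.01).
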