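# capdyn

Seed-based **co-activation pattern (CAP) dynamics** for resting-state fMRI.

`capdyn` implements the full analysis chain used to ask whether activation of a
small seed nucleus (such as the locus coeruleus) is associated with altered
whole-brain state dynamics: which transient brain states co-occur with seed
activation, how often subjects enter them, how long they dwell in them, and how
likely they are to stay in or switch between them — compared between a patient
group and healthy controls with adjustment for demographic, technical and
clinical covariates.

It is aimed at neuroimaging researchers who have already realigned and
normalized their fMRI data and want a tested, reproducible implementation of
the CAP state-dynamics analysis, including a synthetic cohort generator for
validating every stage without access to patient data.

## Method

Given a gray-matter-masked series $X \in \mathbb{R}^{T \times V}$ per subject:

1. **Preprocessing** — nuisance regression (constant/linear/quadratic trends,
   white-matter and CSF mean courses, six motion parameters, global signal),
   DCT-basis high-pass filtering at 0.01 Hz, optional Gaussian smoothing,
   motion scrubbing by Power's framewise displacement
   $FD_t = \sum_i |\Delta d_{i,t}| + r\sum_j |\Delta \theta_{j,t}|$ at
   $FD > 0.5$ mm (frames are flagged, never deleted), and per-voxel z-scoring
   over valid frames.
2. **Frame selection** — frames where the (probabilistically weighted) seed
   time course exceeds $z = 0.84$, the 80th percentile of a standard normal.
3. **Reference CAPs** — pooled control frames are consensus-clustered
   (k-means on random 80% subsamples, 100 repeats) for $K = 2..15$; each $K$
   is scored by the proportion of ambiguously clustered pairs
   $\mathrm{PAC} = \Pr(u_1 < C_{ij} < u_2)$ and the $K$ maximizing
   $1-\mathrm{PAC}$ is kept. A final multi-restart k-means defines the CAP
   maps (z-scored voxel-wise means of member frames, ordered by occupancy).
4. **Assignment** — every patient frame goes to the CAP with maximal spatial
   correlation, or to UNASSIGNED if the correlation falls below that CAP's
   5th-percentile member-correlation threshold.
5. **Dynamics** — per subject: entries (runs of a CAP), mean duration
   (mean run length × TR, seconds), occupancy, and the row-stochastic
   transition matrix $T_{m,n} = \Pr(s_{t+1}{=}n \mid s_t{=}m)$ estimated from
   originally adjacent CAP-labeled frame pairs (gaps censor pairs).
6. **Inference** — per metric, OLS of `metric ~ group + covariates`
   (age, sex, excluded/selected frame counts, medication, depression and
   anxiety scores), Cohen's *d* on covariate-residualized values,
   Benjamini–Hochberg FDR within each metric family. Sign convention:
   patient − control.

The synthetic generator (`capdyn.synth`) plants the exact structure the
analysis assumes — a hidden Markov chain over a quiescent baseline plus
*k* spatial patterns with positive seed loading, motion spikes, nuisance
courses and study-scale covariates — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from capdyn.config import AnalysisConfig
from capdyn.pipeline import run_pipeline
from capdyn.synth import SimConfig, generate_cohort

sim = SimConfig(n_per_group=14, rng_seed=7)   # 14 patients vs 14 controls
bundles = generate_cohort(sim)                # 300 frames at TR 1.3 s each
cfg = AnalysisConfig(k_range=(2, 5), n_subsamples=30, rng_seed=0)
res = run_pipeline(bundles, sim.seed_voxels, cfg)

print("PAC per K:", {k: round(v, 3) for k, v in res.consensus.pac_values.items()})
print("chosen K:", res.chosen_k)
print(res.group_stats["transition"][["adjusted_diff", "p_fdr", "cohens_d"]].round(3))
```

Output:

```
PAC per K: {2: 0.553, 3: 0.0, 4: 0.207, 5: 0.298}
chosen K: 3
                adjusted_diff  p_fdr  cohens_d
metric
T_cap1_to_cap1          0.020  0.700     0.149
T_cap1_to_cap2          0.018  0.700     0.227
T_cap1_to_cap3         -0.038  0.700    -0.275
T_cap2_to_cap1          0.010  0.700     0.146
T_cap2_to_cap2          0.038  0.700     0.329
T_cap2_to_cap3         -0.048  0.423    -0.564
T_cap3_to_cap1         -0.139  0.047    -1.099
T_cap3_to_cap2          0.022  0.700     0.154
T_cap3_to_cap3          0.117  0.216     0.765
```

The PAC table shows the three planted patterns are by far the most stable
partition (PAC = 0 at K = 3), so K = 3 is selected. In the transition-cell
comparison the patient group — simulated with a +0.10 self-transition
(persistence) boost — shows positive adjusted differences on the diagonal
cells and a significantly *reduced* probability of leaving CAP3 for CAP1
after FDR correction; positive `adjusted_diff`/`cohens_d` means the value is
larger in patients.

The same pipeline is available from the shell:

```bash
capdyn simulate --config sim.yaml --out data/
capdyn run-all --data data/ --config analysis.yaml --out results/
```

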