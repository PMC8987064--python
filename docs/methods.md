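# Methods

## Two-state telegraph model of interdomain dynamics

The interdomain distance of a two-domain protease, read out as smFRET
efficiency `E = I_A/(I_A+I_D)`, is modeled as a continuous-time Markov
(telegraph) process with two states S1 < S2 (dimensionless FRET units) and
exponential dwell times at rates k1 (S1→S2) and k2 (S2→S1), both in s⁻¹.
Consequences used throughout:

- stationary occupancies P(S1) = k2/(k1+k2), P(S2) = k1/(k1+k2), so the
  ratio of Gaussian histogram areas equals k1/k2;
- the autocovariance decays as exp(−(k1+k2)·t), so the fitted per-lag
  exponential rate `e` converts to k1+k2 = e/dt (done in exactly one
  place, `estimate_two_state`);
- i.i.d. Gaussian observation noise adds a white component: the normalized
  autocorrelation drops from 1 at lag 0 to d = σ²_signal/(σ²_signal+σ²_noise)
  at lag 1 and decays exponentially thereafter. A power law pinned to
  C(0) = 1 cannot reproduce that amplitude drop, which is why observation
  noise makes the exponential the uniquely preferred model while both
  models describe noiseless curves.

### Simulation

Waiting times are drawn exponentially in continuous time and sampled onto
the frame grid (exact at any dt; no per-frame Bernoulli approximation).
The observation during a frame is the state occupying the frame's start
time; switch frames are rare at k·dt ≈ 0.004–0.008. The initial state is
drawn from the stationary distribution, so there are no equilibration
transients. Noise is applied i.i.d. per frame with a per-state SD; values
are not clipped to [0, 1] by default so Gaussian fits stay unbiased
(clipping is available). The histogram model uses exp(−(x−b)²/c²), so a
fitted width c corresponds to noise SD c/√2
(`sigma_from_gaussian_width`). If the expected dwell falls below dt/10 a
warning (not an error) flags aliasing.

### Estimation

- Histograms: bin width max(0.005, 1/√N); per-bin error √count; counts and
  errors divided by the histogram area (the density integrates to 1 within
  1e-9). Fits are unweighted least squares by default (a `weighted` switch
  uses the √count errors); components are relabeled so b1 < b2, ties in
  peak seeding break toward lower FRET, and initialization is a
  deterministic multi-start (two-peak seeding, symmetric offsets around
  the main peak, eight fixed-seed jittered restarts). An area ratio
  outside [0.02, 50] flags the estimate degenerate ("one-state-looking")
  rather than erroring.
- Correlation: the windowed-mean form — at lag τ both factors subtract the
  mean over their own (N−τ)-point window — computed per trajectory,
  averaged, then normalized once by the averaged lag-0 value. The
  vectorized implementation is held to a literal nested-loop transcription
  at ≤1e-12 relative error.
- Decay fits: power law (a·τ+1)^−b (satisfies C(0)=1, C(∞)=0) and
  exponential d·exp(−e·τ)+f, both by unweighted least squares on the same
  lag points with deterministic multi-start grids. The offset f is
  retained in the fit but excluded from the rate interpretation (the
  two-state closed form has f = 0). Model comparison reports both raw
  residual sums and explained variance (R²) against the curve's total
  variation; the R² gap is the meaningful "both models fit comparably"
  statistic, because a direct ratio of residual sums is degenerate when
  one residual approaches zero.
- Rates: k1 = (k1+k2)·r/(1+r), k2 = (k1+k2)/(1+r) with r = area2/area1.

### Choice of fit range for short trajectories

The windowed-mean correlation estimator is negatively biased by roughly
2·τ_c/(N−τ) (τ_c = correlation time in lags): the subtracted window means
absorb slow fluctuations. For experimental-scale traces the decay fit uses
the conventional lags 1–1000 (the config default). For the simulated
recovery study, trajectories are 2,000 frames with τ_c = 125 lags, so
fitting to lag 1000 would measure the bias, not the kinetics; the recovery
experiments fit lags 1–300 (≈2.4 correlation times, windows ≥1,700
points). With that range the recovered rate sum stays within ±15% of truth
across seeds at the study conditions.

Separately, the closed-form validation of the simulator+estimator chain
(noiseless autocorrelation vs exp(−(k1+k2)τ·dt), max deviation < 0.02 over
lags 1–1000 at 2×10⁵ pooled frames) uses fast kinetics, k1+k2 = 3 s⁻¹ at
dt = 0.1 s. This is a variance-driven choice made from the Bartlett
formula: the estimator's sampling SD is ≈ √(coth((k1+k2)·dt)/N), which
must sit well below the deviation band for the check to test the closed
form rather than sampling noise; at the slow experimental kinetics
(k1+k2 = 0.08 s⁻¹, τ_c = 125 lags) the sampling SD alone is ≈0.025.

## Correlation-map texture entropy

Residue dynamics are reduced to per-frame radial distances from an origin
— by default the per-frame center of mass of the representative (Cα)
coordinates; a residue id may be used instead (the catalytic glutamate is
the origin only for the catalytic-site geometry analysis). The series is
cut into non-overlapping windows (default 200 frames ≙ 1 ns at 5 ps
sampling; a trailing partial window is dropped). Per window, the pairwise
cross-correlation of mean-subtracted series at lag 1 is computed with the
same windowed-mean convention, symmetrized as (C+Cᵀ)/2 (the analysis
thresholds a single value per pair), and averaged over windows; the
averaged matrix is min/max-normalized once to [0, 1]. Lag 1 rather than
lag 0 is used so that static geometry cancels and only propagating
fluctuations score; both are available via the `lag` parameter.

Quantization uses half-open bins [k/10, (k+1)/10) with 1.0 mapped to the
top level. The GLCM counts horizontally adjacent cell pairs in both orders
(the standard symmetric texture GLCM; the offset is configurable), is
normalized to probabilities, and scored as S = −Σ pᵢ ln pᵢ (nats, bounded
by ln 100 for 10 levels). For entropy time series each window's matrix is
normalized on its own scale before quantization; when repeat trajectories
are supplied the windowwise mean and the SD of per-repeat means are
reported, mirroring the three-repeat protocol used for MD error bars.

## Allosteric fingerprints

A candidate residue's motif score is its normalized correlation with the
catalytic motif (residues 218–228, author numbering preserved end to end),
aggregated over motif residues. Two aggregations are provided. Null
calibration on the planted-coupling generator (loading 0, i.e. no real
coupling anywhere) shows that max-aggregation admits ~14% false positives
into the exclusive set: after min/max normalization the matrix maximum
sets the scale, and the extreme cell among 11 motif columns crosses a 0.8
threshold far too often. Mean-aggregation — the coupled-to-the-whole-motif
statistic, which is also what the planted (and biological, shared-mode)
alternative predicts — has a measured false-positive rate of 0 at the same
conditions while recovering planted couplings with Jaccard ≥ 0.8, so it is
the default for set extraction; `aggregate="max"` remains available.

With repeat matrices a residue qualifies in a condition when it passes the
threshold in ≥2 repeats (configurable; capped at the number supplied).
The exclusive (substrate-specific) set is bound \ free restricted to the
hemopexin domain 279–466; unrestricted sets are kept for inspection. The
fixed threshold 0.8 is the default; an experimental density-peak-ratio
rule is provided but its reference maximum must be supplied by the caller
(the rule is not fully determined by a single distribution).

Catalytic-site geometry uses per-residue all-atom centroids when atom
coordinates are available (Cα otherwise, with the mode recorded),
expressed relative to the origin residue so it sits at (0,0,0) each frame;
pairwise motif distances are summarized as mean ± SD over frames and
compared between conditions as per-pair deltas plus a configuration-change
norm.

## Screening post-processing

Vina-output PDBQT is parsed directly (MODEL/ENDMDL blocks, affinity from
the first numeric field of each REMARK VINA RESULT line, atom type from
the trailing PDBQT type column); modes out of affinity order are re-sorted
with a warning. The gap filter keeps ligands with |A1−A2|/|A1| ≥ 0.10
(denominator configurable to |A2|); single-mode ligands are kept and
flagged, zero-affinity ligands skipped with a warning. Closest-residue
assignment minimizes the Euclidean distance over all heavy-atom pairs of
the top mode ("top affinity site" = mode 1; an all-modes-within-1-kcal
option is off by default), breaking ties toward the lower residue id, and
is held to an exhaustive O(n·m) scan in tests. Lead lists are compared as
top-N sets (uniques, pairwise and higher-order intersections). Ligand
identity is the id string; no chemical normalization is attempted.

## Synthetic data: what it emulates, what it does not

- Intensity traces invert the FRET definition (I_A = E·total,
  I_D = total−I_A) around the hidden chain, with optional independent
  per-channel detection noise — anticorrelated by construction. No
  photophysics: no photon statistics, bleaching, blinking, or crosstalk.
- Residue trajectories place residues on a 5 Å grid (geometry is
  irrelevant to the correlation analysis but keeps PDB output plausible)
  and add isotropic white positional jitter (noise_sd, default 1 Å) plus a
  shared latent AR(1) displacement (coefficient 0.9 per frame ⇒ ~10-frame
  correlation time, stationary SD 1 Å) applied along each affected
  residue's outward radial direction, to the motif ∪ allosteric set when
  "bound" and to the motif only when "free". Defaults mirror the MD
  protocol scale: 4,000 frames at 5 ps (20 ns), 200-frame windows. The
  white jitter is deliberately memory-free so that the planted coupling is
  the only lag-1 structure; real Cα fluctuations are themselves
  autocorrelated, so passing recovery tests demonstrates the pipeline's
  statistics, not MD realism.
- Docking cohorts impose exact top-two gaps (A2 = A1·(1−gap)) and place
  top poses within 2 Å of a chosen residue (an exact count of ligands near
  fingerprint residues); secondary modes wander elsewhere. Ground-truth
  labels are emitted alongside every dataset and tests never re-derive
  truth from the data.

All generators are pure functions of (spec, seed), bit-reproducible, with
per-trajectory seeds spawned from the master seed.

## Published reference values

`allofret.reference` carries the published two-state parameters per
substrate (aSyn 0.46/0.52 with decay 0.08 s⁻¹; collagen 0.44/0.55,
0.13 s⁻¹; fibrin 0.42/0.51, 0.08 s⁻¹ — individual rates are not published,
so equal rates are the documented default and are flagged in run logs),
the 30-residue aSyn-specific allosteric list, and the pose GLCM entropies
(3.07/3.28/3.07 nats). The MD-derived values are format/range fixtures:
they depend on specific long MD trajectories and are not desk-scale
reproduction targets, whereas the smFRET-scale quantities are recomputed
from scratch by simulation.

## Problem sizes

Recovery experiments use 100 trajectories × 2,000 frames (2×10⁵ pooled
values, matching the published pooled count); the closed-form check uses
20 × 10,000 frames; fingerprint recovery uses 3 repeats × 4,000 frames ×
60 residues per condition, with 20-seed null calibration; screening
cohorts use 50 ligands × 2 modes × 8 atoms. These sizes make every
statistic's sampling error small relative to its acceptance band while
keeping the whole suite fast on a single CPU.

## Known limitations

- Rates are identified only through histogram areas plus the correlation
  decay; no hidden-Markov segmentation or dwell-time inference.
- Two states only; no photophysical corrections (gamma, crosstalk).
- The correlation estimator's windowed-mean bias at lags approaching the
  trajectory length is documented but not corrected; choose fit ranges a
  few correlation times long.
- The density-peak threshold rule is heuristic and requires an external
  reference scale.
- Synthetic trajectories are statistical stand-ins, not physics; recovery
  results certify the estimators, not force fields.
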