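# allofret

Analysis tools for interdomain dynamics and allosteric communication in
two-domain proteases (built around MMP1 acting on alpha-synuclein
aggregates), combining three stages that are usually scattered across
ad-hoc scripts:

1. **Two-state smFRET kinetics.** Single-molecule FRET trajectories
   (FRET = I_A/(I_A+I_D)) are modeled as a random telegraph process with
   states S1 < S2 and switching rates k1 (S1→S2), k2 (S2→S1). The pooled
   histogram is fitted with a sum of two Gaussians
   `y = a1·exp(−(x−b1)²/c1²) + a2·exp(−(x−b2)²/c2²)`; the mean-subtracted
   autocorrelation (windowed means inside both factors) is fitted with a
   boundary-respecting power law `(a·τ+1)^−b` and an exponential
   `d·exp(−e·τ)+f`. For a two-state process
   `k1/k2 = area(S2)/area(S1)` and `k1+k2` is the exponential decay rate,
   which identifies both rates. A continuous-time simulator with Gaussian
   observation noise closes the loop (input vs recovered parameters).
2. **Correlation-map entropy.** Per-residue radial coordinate series from
   MD-style trajectories are cut into windows; residue-pair
   cross-correlations at lag 1 are averaged, min/max-normalized to [0, 1],
   quantized into 10 levels, summarized as a 10×10 gray-level co-occurrence
   matrix (GLCM), and scored by Shannon entropy `S = −Σ pᵢ ln pᵢ`;
   coherent interdomain motion lowers S.
3. **Allosteric fingerprints and screening post-processing.** Residues
   whose normalized correlation with the catalytic motif (HELGHSLGLSH,
   author-numbered 218–228 around E219) exceeds 0.8 only in the
   substrate-bound enzyme — restricted to the hemopexin domain (D279–C466)
   — form the substrate-specific fingerprint. Vina-style docking results
   are filtered by a ≥10% top-two-mode affinity gap, annotated with the
   closest receptor residue, and intersected with the fingerprint to pick
   substrate-specific leads.

Everything is exercisable on synthetic data with known ground truth (a
planted shared-factor coupling between motif and designated allosteric
residues; docking cohorts with planted gaps and pose placement), so the
whole pipeline is testable without downloads.

The analysis stages are scikit-learn style estimators
(`TwoStateEstimator`, `CorrelationEntropy`, `FingerprintExtractor`,
`LeadSelector`) with fitted attributes, composable with sklearn tooling;
module-level functions expose the individual steps.

## Worked example

```python
from allofret import TwoStateEstimator, simulate_ensemble
from allofret.reference import two_state_params

# measured condition: active enzyme on aSyn aggregates, no ligand
params = two_state_params("asyn_active", sigma=0.03)
trajs = simulate_ensemble(params, n_traj=100, n_frames=2000, dt=0.1,
                          with_noise=True, seed=1)
est = TwoStateEstimator(dt=0.1, max_lag=300, fit_max_lag=300).fit(trajs)
print(f"S1 = {est.S1_:.3f}, S2 = {est.S2_:.3f}")
print(f"k1/k2 = {est.rate_ratio_:.2f}, k1+k2 = {est.rate_sum_:.4f} /s")
print(f"preferred decay model: {est.decay_fits_.preferred}")
```

prints

```
S1 = 0.459, S2 = 0.519
k1/k2 = 0.97, k1+k2 = 0.0755 /s
preferred decay model: exponential
```

The simulation was driven by S1 = 0.46, S2 = 0.52 and k1 = k2 = 0.04 s⁻¹:
the pooled double-Gaussian fit recovers both states to ±0.01 even though
they sit only two noise SDs apart, the area ratio recovers k1/k2 ≈ 1, and
the exponential decay recovers k1+k2 = 0.08 s⁻¹ within a few percent — and
the exponential beats the power law, as expected for a noisy two-state
process.

A CLI mirrors the stages:

```bash
allofret --seed 1 --out-dir out simulate --n-traj 10
allofret --out-dir out entropy --trajectory trajectory.pdb
allofret --out-dir out fingerprint --bound b1.tsv --bound b2.tsv --free f1.tsv
allofret --out-dir out screening --results lig1.pdbqt --receptor receptor.pdb
```

Each run writes TSV result tables plus a JSON run log (seed, config hash),
and fixed seed + fixed inputs reproduce byte-identical tables.

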