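# nirsnet

Analysis pipeline for multi-channel prefrontal **fNIRS** recordings of a
working-memory block paradigm, built for studies that track cognitive
status — e.g. mild cognitive impairment (MCI) patients against healthy
controls (HC) — through hemodynamic responses, functional connectivity,
and graph-theoretic network metrics. Because clinical recordings of this
kind are rarely deposited, the package ships a synthetic cohort generator
with known ground truth, so every stage of the chain is testable end to
end.

The chain, in the order it runs:

1. **Optics** — raw two-wavelength (760/850 nm) intensities → optical
   density → ΔHbO/ΔHbR (µM) via the modified Beer–Lambert law
   `ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ)`, then a
   zero-phase 4th-order Butterworth band-pass (0.026–0.15 Hz) removing
   cardiac, respiratory and drift components.
2. **Activation** — a designed hemodynamic response function (canonical
   double-gamma, peak 6 s, convolved with the 24-s task boxcar) fitted
   per channel by robust IRLS (bisquare, c = 4.685): slope β, robust SE,
   t = β/SE, plus block averages and min–max-normalized t-maps over the
   optode plane.
3. **Connectivity** — pairwise Pearson r over the resting state or the
   task session; Fisher z = atanh(r) for averaging and testing;
   binarization by fixed threshold (0.8) or proportional sparsity (the
   `round(s·N(N−1)/2)` strongest edges).
4. **Graph metrics** — degree `D(i) = Σⱼ a(i,j)`, nodal efficiency
   `E_nodal(i) = (N−1)⁻¹ Σ_{j≠i} 1/d(i,j)`, clustering
   `C(i) = 2Lᵢ/(Zᵢ(Zᵢ−1))`, global efficiency `E_glob = mean E_nodal`,
   local efficiency `E_loc = N⁻¹ Σᵢ E_glob(Gᵢ)`, and small-worldness
   `σ = (K/C_rand)/(L/L_rand)` against degree-preserving rewired nulls —
   swept over sparsity 0.50–0.90 (step 0.05) and summarized mean ± SD.
5. **Group statistics** — pooled/Welch two-sample and paired t-tests (raw
   or summary form), mean-z connectivity comparison, metric–score Pearson
   correlation, and the power-based sample-size computation
   `n = ⌈2(z₁₋α/₂+z₁₋β)²/d²⌉` with dropout inflation.

The default configuration matches the study settings throughout: 7.81 Hz
sampling, 20 channels from 8 emitters and 7 detectors at 2.5–3.0 cm, a
4-min resting state plus nine 38-s trials (342 s task session), fixed
threshold 0.8, sparsity grid 0.5–0.9, α = 0.01.

## Worked example

```python
import nirsnet as nn

schedule = nn.make_default_schedule()
profile = nn.default_profiles()[0]          # HC: 0.40 uM evoked amplitude
rec, truth = nn.simulate_subject(profile, schedule=schedule, seed=7)
hemo = nn.preprocess_recording(rec)         # OD -> MBLL -> band-pass

reg = nn.build_dhrf(schedule, hemo.fs)
act = nn.estimate_activation(hemo.hbo, reg, hemo.channels)
print(act.table.head(3).to_string(index=False))
print("active channels:", act.table.loc[act.table.active, "channel"].tolist())

fc = nn.fc_matrix(hemo, segment=schedule.segments["resting"])
print(f"mean resting r: {fc.off_diagonal().mean():.3f}")

sweep = nn.sparsity_sweep(fc, n_nulls=50, seed=0)
print(sweep.mean_sd().round(3))
```

prints

```
channel     beta       se         t  active
   CH01 0.118977 0.005886 20.211908    True
   CH02 0.105607 0.005985 17.645069    True
   CH03 0.017134 0.004707  3.640316    True
active channels: ['CH01', 'CH02', 'CH03', 'CH04', 'CH05', 'CH09', 'CH14', 'CH16', 'CH19']
mean resting r: 0.478
                             mean     sd
global_efficiency           0.848  0.071
local_efficiency            0.908  0.039
char_path_length            1.313  0.154
mean_clustering             0.817  0.076
small_worldness             1.103  0.081
small_worldness_normalized  0.524  0.018
```

The fitted β on the filtered data is attenuated relative to the 0.40 µM
generative amplitude (the 0.026-Hz high-pass removes part of the block
response), but the eight truly active channels (1, 2, 4, 5, 9, 14, 16, 19)
all reach large t-values; CH03 is a false positive at α = 0.01 — the
session-wise GLM makes no serial-correlation correction, a documented
limitation. The mean resting correlation 0.478 reflects the latent 0.60
coupling attenuated by in-band noise, and the sparsity sweep reports the
network metrics with their spread across threshold levels.

A shell interface mirrors the stages
(`nirsnet simulate | preprocess | activate | connect | metrics | stats |
report`, each with `--config`, `--seed`, `--out`); `nirsnet report` runs
everything on a simulated cohort and writes all artifacts plus a run
manifest with the configuration digest.

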