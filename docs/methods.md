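# Methods

`nirsnet` implements a complete analysis chain for multi-channel prefrontal
fNIRS recordings of a working-memory block paradigm — the kind of protocol
used to track cognitive status in mild cognitive impairment (MCI) against
healthy controls (HC) — together with a synthetic cohort generator that
provides ground-truth recordings for every stage.

## The measurement model

A continuous-wave fNIRS channel measures light intensity at two wavelengths
(760 and 850 nm) between an emitter and a detector placed 2.5–3.0 cm apart
on the scalp. Intensity is converted to optical-density change against a
baseline window, `ΔOD(t) = −log10(I(t)/I₀)`, and the modified Beer–Lambert
law (MBLL) maps the two ΔOD series to oxy-/deoxy-hemoglobin concentration
changes (ΔHbO, ΔHbR, in µM) by solving, per time point, the 2×2 system

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ)

with ε the molar extinction coefficients (defaults from the standard Prahl
compilation: 586/1548.52 at 760 nm, 1058/691.32 at 850 nm, in 1/(M·cm)),
`d` the separation (default 3.0 cm) and DPF the differential pathlength
factor (default 6.0 at both wavelengths). Because the acquisition software
used in such studies does not document partial-volume handling, the
absolute µM scale is convention-dependent; all defaults are explicit and
overridable in `OpticalGeometry`. The baseline window for I₀ defaults to
the resting-state segment.

Physiological nuisance — cardiac (~1.1 Hz), respiration (~0.25 Hz), Mayer
waves (~0.1 Hz) and slow drift — is removed by a 4th-order Butterworth
band-pass between 0.026 and 0.15 Hz, realized as cascaded low-pass and
high-pass sections, each applied forward–backward (zero-phase), which
preserves response timing for the subsequent regression at the cost of
squaring the magnitude response. The low cut is 1/38 Hz, the reciprocal of
one trial period, so the evoked response itself passes. Downstream analysis
uses ΔHbO only (better SNR than ΔHbR); ΔHbR is carried through conversion
and is selectable.

## Paradigm and activation analysis

The paradigm is a 4-min resting state followed by nine 38-s trials (8 s
encoding, 14 s retention, 2 s probe — a 24-s task block — then 14 s rest,
with a 2-s ready cue at the end of the preceding rest) and a 30-s
post-rest: 612 s at 7.81 Hz.

The designed hemodynamic response function (dHRF) convolves a canonical
double-gamma HRF with a unit boxcar spanning each 24-s task block. The
double-gamma uses gamma densities with unit scale and shape `peak + 1`, so
the response mode falls exactly at the configured time-to-peak (default
6 s; undershoot at 16 s with ratio 1/6). The regressor is normalized to
unit peak so the regression slope reads directly as an evoked amplitude in
µM. The 24-s block is modeled as a single boxcar rather than separate
encode/retain/probe regressors, matching a single-dHRF fit; the phase-wise
design is possible by editing the event schedule.

Channel activation is estimated session-wise by iteratively reweighted
least squares with Tukey bisquare weights (tuning constant 4.685, the
95%-efficiency default of the common robust-fit routines), via
`statsmodels` RLM, y = β₀ + β·dHRF + ε; t = β/SE with the robust SE. A
channel is called active when t exceeds the upper-tail critical value of
the t distribution at α = 0.01. Whether published t-values of this kind
come from trial-wise or session-wise fits is generally unstated;
session-wise is implemented. Block averages epoch ΔHbO over
[−2 s, +38 s] around task onsets, subtract each epoch's pre-onset mean,
and report the point-wise mean ± SD. Activation maps interpolate channel
t-values over the 2-D montage plane with a thin-plate-spline RBF (exact at
the channels, hence rank-preserving there — any smooth interpolant with
that property would do) and min–max normalize to [0, 1]; a spread-free map
is all zeros by convention.

## Connectivity and network analysis

Functional connectivity is the Pearson correlation of channel ΔHbO over a
segment — the resting state or the full task session (inter-trial rests
included; the task response is not regressed out, a documented
limitation). Matrices are Fisher-transformed (z = atanh r, r clipped to
±(1−1e−7), zero diagonal) before averaging or testing, because r is not
additive; group averages are computed in z-space and mapped back. Signed r
(not |r|) feeds both binarization modes: a fixed threshold (default 0.8)
keeps edges with r > 0.8, and a proportional (sparsity) threshold keeps
the `round(s·N(N−1)/2)` strongest edges (round-half-up; ties broken by
channel order). Zero-variance channels get zeroed rows/columns with a
warning.

Graph metrics on the binary, undirected networks: degree; nodal efficiency
(mean inverse shortest-path length to all other nodes, with 1/∞ = 0);
clustering (triangle fraction, 0 for degree < 2); global efficiency (mean
nodal efficiency); local efficiency (mean global efficiency of
neighbor-induced subgraphs, 0 below 2 nodes); characteristic path length
on the largest connected component; and small-worldness
σ = (K/C_rand)/(L/L_rand) against degree-preserving Maslov–Sneppen
rewired nulls (10·|E| swap attempts per null, 100 nulls by default,
seeded). Since some toolchains report a 0–1 bounded small-world index
while the raw σ exceeds 1 for small-world networks, the normalized value
σ/(1+σ) is emitted alongside σ. The sparsity sweep evaluates the full
metric set on the grid 0.50–0.90 in steps of 0.05 and summarizes each
metric as mean ± SD across levels.

Note that a proportional threshold fixes the edge count: at N = 20 and
s ≥ 0.5 the graph has ≥ 50% density, almost always diameter ≤ 2, and so
global efficiency is bounded below by roughly 0.7 whenever the network is
connected. Efficiency differences between such networks are therefore
driven almost entirely by nodes that remain isolated at a given level —
clinical reports of much lower efficiency percentages arise from other
thresholding conventions and are not reproducible under this one.

## Group statistics

Two-sample comparisons default to the pooled Student t-test (Welch by
flag) and accept either raw values or printed summary statistics
(mean/SD/n) — the two routes agree exactly for pooled tests. Paired
comparisons use the t-test on differences; zero-variance differences are
flagged degenerate rather than returning an arbitrary p. Connectivity
collections are compared by reducing each subject's matrix to its mean
upper-triangle Fisher z and testing those scalars. Metric–score
correlation is plain Pearson. No multiple-testing correction is applied by
default (fixed α = 0.01 throughout); a Bonferroni option exists for
element-wise comparisons. The power-based sample size for a two-group mean
comparison is n = ⌈2(z₁₋α/₂ + z₁₋β)²/d²⌉ per group (d = δ/σ), inflated by
an anticipated dropout rate: ⌈n/(1−dropout)⌉.

## The synthetic cohort

Per subject and channel, ΔHbO(t) = A·dHRF(t) + background(t) + noise(t);
ΔHbR = −evoked/3 plus independent background and noise at 1/3 scale
(typical anticorrelation; ΔHbR exists to exercise the two-wavelength
forward model). The signal is pushed through the forward MBLL to
two-wavelength intensities (I₀ = 1), so the full inversion chain is
exercised.

* **Evoked component.** Amplitude A on the active channels (1-based
  channels 1, 2, 4, 5, 9, 14, 16, 19 — a dorsolateral/frontal selection),
  with 8% between-subject variability.
* **Correlated background.** White noise mixed through the spectral square
  root of the group's latent correlation matrix, smoothed into roughly the
  analysis band (0.015–0.2 Hz, 2nd order) with a *common* filter so
  cross-channel correlations are preserved, and scaled to 0.2 µM SD. The
  empirical correlation of a long noiseless background converges to the
  latent matrix; with in-band white noise present the measured
  correlations are attenuated by a constant factor (~0.67 at the default
  noise levels), which preserves rank order and group contrasts.
* **Noise.** Sinusoids at 1.1/0.25/0.10 Hz (amplitudes 0.20/0.10/0.05 µM,
  random phase per channel), a random-walk drift (0.05 µM/√s) and white
  noise (0.03 µM) — all chosen so the band-pass removes them and so their
  in-band leakage is small against the 0.2 µM background.
* **Groups.** Four profiles ordered HC > MCI-1 > MCI-2 > MCI-0 in evoked
  amplitude (0.40/0.30/0.20/0.10 µM), in overall coupling strength
  (0.60/0.55/0.45/0.35), and in network integration. Integration is
  encoded as an *isolation schedule*: under proportional thresholding the
  retained edge count is fixed, so group differences in sweep-averaged
  global efficiency can only come from channels whose correlations rank
  below the coupled core and which therefore stay isolated until the edge
  budget exceeds the core's pair count. HC has no degraded channels;
  MCI-1 one decoupled channel (isolated across the entire sweep, since
  C(19,2) = 171 ≥ every edge budget on the grid); MCI-2 one decoupled
  plus one semi-coupled (0.10) channel; MCI-0 two decoupled channels with
  ordered residuals (0.02/0.0) plus one semi-coupled. The coupling-tier
  gaps exceed three standard deviations of the group-averaged pairwise z
  noise at n = 11, so the edge ranking — and with it the efficiency
  ordering — is recovered stably. The degraded channels (8–10) sit in the
  set reported as weak in impaired groups in comparable studies.
* **Seeds.** Per-subject seeds derive from
  SHA-256(master seed, group label, subject index) mod 2³¹: reproducible,
  collision-free streams; identical (profile, seed) pairs give
  bit-identical recordings.

What the generator does *not* emulate: motion artifacts, scalp/skull
optics and partial-volume effects, systemic superficial physiology shared
between channels, task-correlated noise, habituation or fatigue across
trials, and non-stationary connectivity. Passing the recovery tests
therefore demonstrates the correctness of the analysis chain under the
stated generative model, not clinical performance on real recordings.

## Montage

The 20-channel prefrontal fixture places 8 emitters and 7 detectors in two
rows 3.0 cm apart (upper: E1 D1 E2 D2 E3 D3 E4; lower: D4 E5 D5 E6 D6 E7
D7 E8), with FpZ as the reference landmark under the array center. The 13
horizontally adjacent and 7 vertical emitter–detector pairs give 20
channels, every separation exactly 3.0 cm. Published configurations of
this kind are shown only schematically, so the exact pairing here is a
reconstruction satisfying the stated counts and separations; coordinates
are a flat 2-D head-schematic frame in cm, channel numbering 1-based.

## Numerical choices and conventions

* Matrix square root of latent correlations by spectral decomposition
  (tolerates semi-definite matrices); validity checked by symmetry, unit
  diagonal and smallest eigenvalue ≥ −1e−8.
* Robust IRLS: convergence at coefficient change < 1e−8 or 50 iterations.
* r clipped to ±(1−1e−7) before atanh; duplicated channels stay finite.
* Proportional threshold edge count: round-half-up; ties broken by (row,
  column) order — both documented because `round` alone is ambiguous at
  .5.
* Unreachable pairs contribute 0 to efficiencies; characteristic path
  length is computed on the largest component; small-worldness is flagged
  undefined for networks with < 2 edges or degenerate nulls.
* Filter preconditions (0 < low < high < fs/2) are validated with the
  sampling rate in the message; the pipeline validates its configuration
  before any stage runs.
* Problem sizes in the shipped tests and the acceptance script: cohorts of
  4 groups × 11 subjects over 20 master seeds for ordering recovery, 2 ×
  11 over 20 seeds for connectivity-difference power, 2000 replicates for
  test calibration, 50 random graphs (N ≤ 12) for oracle equivalence —
  sizes chosen to match the study's group size (11 analyzed per group)
  while keeping a desk-scale runtime.

## Known limitations

* Session-wise GLM without prewhitening: serial correlation inflates
  nominal t-values; only relative comparisons and the robust weighting are
  relied upon.
* Task-segment connectivity includes the evoked response and inter-trial
  rests; no task regression is performed before correlation.
* The absolute µM scale depends on the DPF/partial-volume convention.
* Proportional thresholding compresses the attainable global-efficiency
  range (see above); fixed-threshold binarization is provided for
  analyses that need level sensitivity.
* Printed-summary t-tests can disagree in the second decimal of p with
  tests on the underlying raw data when the summaries are rounded.
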