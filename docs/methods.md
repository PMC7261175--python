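# Methods

## The model

A molecule carries one donor and one acceptor dye and interconverts between
two conformations, open (apparent FRET `e_open`, default 0.4) and closed
(`e_closed`, default 0.6), as a continuous-time Markov chain with rates
`k_oc` (open→closed) and `k_co` (closed→open). The stationary closed
occupancy is `k_oc/(k_oc+k_co)`. The camera integrates for `dt = 0.1 s`
per frame (100 ms exposure), so each frame reports the *time-weighted mean*
FRET over its exposure: the simulator draws exact Gillespie event times and
bins them, which reproduces the real instrument's behavior that exchange
much faster than the frame interval collapses to an averaged value and very
slow exchange is censored by the finite observation window.

Emission is a constant total intensity `i_total` split `E : (1-E)` between
acceptor and donor, plus a constant per-channel `background` and additive
Gaussian read noise `sigma_read` per channel per frame. Each dye bleaches
in a single step after an exponential waiting time (`bleach_rate_donor`,
`bleach_rate_acceptor`, s⁻¹, independent). After acceptor bleach the donor
recovers the full intensity; after donor bleach both channels fall to
background. Apparent FRET is analyzed uncorrected (no gamma/crosstalk
correction); an optional `leakage` parameter (default 0) mixes donor signal
into the acceptor channel for sensitivity studies.

## Analysis chain

1. **QC** (`qc`): noise SD is estimated per channel as
   `1.4826 * MAD(diff(y)) / sqrt(2)`, robust to steps. Changepoints come
   from greedy binary segmentation (best least-squares single split,
   recursively, minimum segment 2 frames) and count as steps when the
   fitted level change exceeds `step_sigma = 3` noise SDs; a downward step
   is the terminal bleach when the mean from the step to the end of the
   trace is within 2 SDs of background. A trace is accepted when
   (a) the donor shows exactly one downward step, terminal, and the
   acceptor at most one, **or** (b) the first-difference Pearson
   correlation over the pre-bleach window is ≤ `anticorr_thresh = -0.3`
   with total-intensity CV ≤ `cv_max = 0.2`. The OR is the literal
   selection rule; `strict_and` requires both bleach steps instead.
   Rejections carry one of: `multi_step`, `no_signal`, `too_short`,
   `no_anticorr`, `high_cv`.
2. **FRET** (`fret`): `E = (I_A - bg_A) / ((I_A - bg_A) + (I_D - bg_D))`
   per frame, background subtraction off by default (the published formula
   is the raw ratio), frames from the first bleach onward excluded, frames
   with non-positive denominator excluded and counted, values clamped to
   [-0.5, 1.5] for reporting. Static/dynamic classification median-filters
   the series (3 frames) and idealizes it by hysteresis thresholding at the
   state midpoint with a ±0.05 dead band; a transition counts when both
   flanking dwells last ≥ 3 frames. An HMM was deliberately not used: only
   the presence and count of transitions is reported, not rate constants.
3. **Histogram** (`histogram`): per-frame pooling over accepted traces
   (a per-trace-mean mode exists for sensitivity analysis), bin width 0.02
   over [-0.1, 1.1], five-point unweighted moving average with truncated
   edge windows, then division by the smoothed maximum. The normalized
   curve is fit with one Gaussian (center free in [0.3, 0.7]) and with two
   (centers bounded to [0.30, 0.50] and [0.50, 0.70], widths in
   (0.01, 0.14], amplitudes ≥ 0; data-derived deterministic initial
   values). Two components are kept only when they improve residual RMS by
   ≥ 20% and each carries ≥ 5% of the total area. Centers are bounded, not
   fixed, because "centered at 0.4 and 0.6" admits either reading; bounding
   lets the fit report the realized peak positions. The closed fraction is
   the ≥ 0.5-center area over the summed areas; a lone component counts as
   fully closed if its center is ≥ 0.5, else fully open.
4. **Statistics** (`popstats`): Welch's unpaired two-tailed t-test with
   Welch–Satterthwaite degrees of freedom on replicate closed fractions
   (separate experiments as replicates). Ladder: n.s. ≥ 0.05, * < 0.05,
   ** < 0.005, *** < 0.0005, with a boundary p taking the less significant
   label. No multiple-testing correction — comparisons are per-pair by
   design. Degenerate zero-variance groups: equal means give t = 0, p = 1;
   unequal means report the smallest positive float.
5. **Binding** (`binding`): anisotropy titrations use the ligand-depletion
   quadratic bound fraction
   `FB = ((P+L+K_D) - sqrt((P+L+K_D)^2 - 4PL)) / 2L`, appropriate because
   probe (≈10 nM) and K_D (≈120 nM) are within an order of magnitude;
   population titrations use the hyperbola `F0 + (Fmax-F0)·c/(K_D+c)`.
   Fits are unweighted least squares (lmfit) with data-derived starts; a
   response span below 3× the estimated noise raises an unresolvable-K_D
   error. ΔΔG = RT·ln(K_D,weak/K_D,tight) with R = 1.987×10⁻³
   kcal mol⁻¹ K⁻¹ and T = 298 K by default. Labeling efficiencies divide
   each dye concentration (A_dye/ε_dye; ε_Cy3 = 150 000, ε_Cy5 = 250 000
   M⁻¹cm⁻¹) by the protein concentration from A280 after subtracting the
   dyes' 280 nm contributions (fractions 0.08 / 0.05 of their visible
   bands, conventional vendor values, config-exposed; ε_protein = 17 420
   M⁻¹cm⁻¹).

## What the generator emulates — and does not

Emulated: Markovian two-state switching with exposure averaging; constant
total intensity with Gaussian camera noise; independent exponential
single-step photobleaching; static molecules as rate-zero chains (their
histograms still carry shot noise); two-pair "aggregate" contaminants with
staircase bleaching; population shifts governed by a single-site binding
law (for dynamic titration traces the total switching rate is preserved
and the stationary occupancy follows the binding mixture — ligand binding
shifts the equilibrium rather than freezing molecules).

Not emulated: camera movies and spot detection, dye blinking and triplet
photophysics, spectral crosstalk beyond a constant leakage factor,
intensity drift, heterogeneous brightness between molecules, and
sub-frame kinetic inference. Passing tests therefore validate the
*analysis chain* under the stated generative assumptions; they do not
certify performance on traces whose noise violates them (e.g. strong
blinking would defeat the single-step bleach criterion).

Trace intensity scale and noise are not constrained by published values;
the defaults `i_total = 1000` counts and `sigma_read = 40` (SNR 25) are a
plausible EMCCD operating point and are config-exposed. Default bleach
rates (donor 0.03, acceptor 0.05 s⁻¹) put typical pre-bleach observation
in the 0.1–50 s range at 0.1 s frames.

## Problem sizes and statistical design of the validation suite

* Closed-fraction recovery runs 300 accepted traces per condition at
  p_closed ∈ {0.33, 0.5, 0.66, 0.7, 1.0}, using fully dynamic traces with
  total switching rate 2 s⁻¹. Dynamic traces are the low-variance design:
  each molecule time-averages its own state occupancy, so the estimator SD
  is ≈ 0.01–0.02, well inside the ±0.05 recovery band; a purely static
  mixture at the same trace count has an irreducible trace-sampling SD of
  ≈ 0.03–0.04 and would make the band a ~1.3σ statement.
* Dynamic-fraction recovery uses 500 traces, k = 0.2 s⁻¹, 2000-frame
  movies with 0.005 s⁻¹ bleaching: the probability that a dynamic molecule
  shows no transition before bleaching is ≈ λ/(λ+k) ≈ 5%, so the
  finite-window censoring (the same effect that hides very slow exchange
  from the real instrument) costs ~0.015 of the 0.30 target.
* Changepoint localization uses 1000 planted steps at SNR 10; occupancy
  checks use 200 paths × 600 frames per rate pair; Welch calibration uses
  10⁴ null replicates of 5-vs-5 samples.
* K_D recovery pools triplicate 12-point log-spaced titrations at 5%
  response noise. A single such titration fundamentally cannot determine
  K_D to 10%: the Fisher-information bound for the 3-parameter fit gives a
  relative SE of ≈ 19%, so replication (matching how such experiments are
  actually run) is part of the design; the pooled fit has SE ≈ 11% and is
  checked at 15%.

The whole suite runs in well under a minute on one CPU.

## Known limitations

* The binary trace container is a documented stand-in dialect, not a
  reverse-engineered acquisition format; trace ids are not preserved in it.
* The anti-correlation criterion weakens for slow switchers (few
  transitions per trace dilute the first-difference covariance); such
  traces are retained only via the bleach criterion, and analyses that
  need unbiased dynamic fractions should classify all traces rather than
  the QC-selected subset.
* Model selection between one and two Gaussians uses a fixed RMS
  improvement rule, not an information criterion; with heavily overlapping
  states (separation ≲ width) the decomposition is not identifiable and
  the closed fraction should not be trusted.
* No dwell-time or rate-constant estimation, no >2-component mixtures, no
  Hill/competition binding models.
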