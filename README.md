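# smfretpop

Single-molecule FRET (smFRET) analysis of two-state conformational
populations, built for tandem-domain proteins such as the U2AF2 RRM1–RRM2
module of the U2AF splicing-factor heterodimer, which interconverts between
an **open** (side-by-side, RNA-bound, apparent FRET ≈ 0.4) and a **closed**
(back-to-back, RNA-free, apparent FRET ≈ 0.6) domain arrangement. Given
per-molecule donor (Cy3) and acceptor (Cy5) intensity time series from a
TIRF microscope, the package answers: *what fraction of molecules is in the
closed conformation, does that fraction differ between conditions, and how
does ligand binding shift it?*

It is aimed at single-molecule biophysicists who have already reduced
camera movies to per-spot intensity traces and want a scriptable, tested
alternative to ad-hoc IDL/MATLAB/Origin workflows.

## What it computes

* **Trace QC** — a trace is analyzable when it shows single photobleaching
  steps for each dye and/or anti-correlated donor/acceptor changes at
  constant total intensity. Steps are found by binary-segmentation
  changepoint fitting with a 3σ magnitude rule; anti-correlation is the
  Pearson correlation of the channels' first differences.
* **Apparent FRET** — per frame, E^app = I_A / (I_A + I_D), truncated at
  the first photobleach; traces are classified static vs dynamic by
  median-filtered hysteresis idealization between the 0.4 and 0.6 states.
* **Population histograms** — pooled per-frame E^app values, smoothed with
  a five-point window and normalized to a unit maximum, then decomposed
  into one or two Gaussians with centers bounded near 0.4 / 0.6 and widths
  ≤ 0.14. The **closed fraction** is
  area(μ≈0.6) / [area(μ≈0.4) + area(μ≈0.6)].
* **Statistics** — replicate closed fractions are compared with the
  unpaired two-tailed Welch t-test; p-values map to
  n.s. (≥ 0.05), \* (< 0.05), \*\* (< 0.005), \*\*\* (< 0.0005).
* **Binding** — K_D from fluorescence-anisotropy titrations (single-site
  ligand-depletion quadratic) or from FRET-population titrations (binding
  hyperbola); fold changes and ΔΔG = RT·ln(K_D ratio); dye labeling
  efficiencies from a 280/550/650 nm absorbance spectrum.
* **Synthetic data** — a Gillespie two-state simulator with
  exposure-averaged FRET, camera noise, exponential single-step
  photobleaching, static/dynamic/aggregate trace mixtures and binding-law
  titrations, so every stage is testable against known ground truth.

## Worked example

```python
import numpy as np
from smfretpop import (
    KineticParams, EmissionParams, simulate_dataset,
    compute_fret, build_histogram, fit_components, fold_change, delta_delta_g,
)
from smfretpop.qc import qc_all

# two-state protein, 66% closed at equilibrium, switching at 2 per second
kin = KineticParams(k_oc=1.32, k_co=0.68)   # stationary closed occupancy 0.66
emi = EmissionParams()                      # 1000 counts/frame, sigma 40, 0.1 s frames
traces, truth = simulate_dataset(kin, emi, n_traces=300, frac_dynamic=1.0, seed=11)

series = [compute_fret(trace, verdict)
          for trace, verdict in zip(traces, qc_all(traces)) if verdict.accepted]
print(f"accepted {len(series)}/{len(traces)} traces")

hist = build_histogram(series)              # 5-point smoothed, max-normalized
fit = fit_components(hist)                  # bounded two-Gaussian decomposition
for c in fit.components:
    print(f"component: center={c.center:.3f} width={c.width:.3f} area={c.area:.3f}")
print(f"closed fraction = {fit.closed_fraction:.3f} (truth 0.66)")

print(f"fold change 120 -> 600 nM: {fold_change(120, 600):.1f}")
print(f"ddG = {delta_delta_g(120, 600, 298):.2f} kcal/mol")
```

prints

```
accepted 250/300 traces
component: center=0.404 width=0.046 area=0.058
component: center=0.598 width=0.045 area=0.116
closed fraction = 0.665 (truth 0.66)
fold change 120 -> 600 nM: 5.0
ddG = 0.95 kcal/mol
```

The simulator generated 300 dynamic traces whose stationary closed
occupancy is 0.66; QC accepted 250 (the rest bleach too early or show too
few anti-correlated transitions), and the two-Gaussian decomposition of the
pooled FRET histogram recovers the closed fraction to 0.665. The last two
lines are the thermodynamic arithmetic for a five-fold affinity difference:
RT·ln(5) ≈ 0.95 ≈ 1 kcal/mol at 298 K.

## Command line

A thin CLI mirrors the library:

```sh
smfretpop simulate --n-traces 200 --frac-dynamic 1 --seed 1 --out traces.csv
smfretpop qc traces.csv --out qc.csv
smfretpop fret traces.csv --out fret.csv
smfretpop hist fret.csv --out hist.csv --out-fit fit.json
smfretpop kd titration.csv --mode anisotropy --probe-nm 10
smfretpop compare --replicates wt.csv mut.csv
```

Trace files are long-format CSV (`trace_id,frame,time_s,donor,acceptor`) or
a documented little-endian binary container (`--format traces`).

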