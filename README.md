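# quadpop

Population dynamics of G-quadruplexes from single-molecule force
spectroscopy.

During transcription of a G-rich duplex, the non-template DNA strand and the
nascent RNA transcript can fold into a mixture of structures at one locus: a
DNA G-quadruplex (GQ), a partially folded G-triplex (GT), and DNA/RNA hybrid
G-quadruplexes (HQ) built from two or three DNA G-tracts plus RNA G-tracts.
Optical-tweezers pulling of a transcription-stalled construct resolves this
mixture one molecule at a time: each unfolding event in a force–extension
(F–X) ramp releases a contour length ΔL that fingerprints the species, its
rupture force measures mechanical stability, nonequilibrium work gives
thermodynamic stability, and force-jump (pump–probe) cycles time the
refolding. `quadpop` implements that entire analysis chain for researchers
working with such recordings, together with a seeded physics-based trace
generator for validation.

## The analysis

**Contour-length change.** The tether obeys an extensible worm-like chain;
the extension-per-contour ratio at tension *F* is

    Δx/ΔL = 1 − (1/2) √(k_B T / (F P)) + F/S

with persistence length *P* = 50.9 nm, stretch modulus *S* = 1168 pN and
*T* = 296.15 K. An event's ΔL is measured two ways — from the two filtered
data points flanking the rupture (translated to equal force along the WLC)
and from the difference of WLC contour-length fits to the stretch and relax
branches — and converted to a nucleotide count via
*n* = round((ΔL + w)/ℓ) with ℓ = 0.44 nm/nt and folded width w = 2.3 nm,
so ΔL = 1.8/3.8/6.0 nm ↦ 9/14/19 nt.

**Population deconvolution (PoDNano).** A Gaussian KDE of the pooled ΔL
sample (Silverman bandwidth, held fixed) is bootstrapped 3000×; KDE peaks
reproduced in ≥ 50% of resamples are retained with percentile CIs. A
Gaussian mixture initialized at the retained peaks assigns each event to a
population; percent formation is events-per-population over all curves.
The ~4 nm population (3G-HQ and GT overlap) is split using the GT:GQ ratio
of the 7-deaza-GTP condition, where no HQ can form:
GT% = GQ% × (GT/GQ)_deaza, 3G-HQ% = peak total − GT%. Overlapping
rupture-force populations are separated by seeded random deconvolution
(each event drawn into a class at its 2-component-mixture posterior).

**Energetics.** Each rupture contributes work W = F·Δx minus the conjugate
stretching work ∫₀^F x_ss(F′)dF′ of the released strand (inextensible WLC,
P = 1.0 nm); the unfolding free energy is the Jarzynski estimator
ΔG = −k_B T ln⟨e^(−W/k_B T)⟩ with a subsample-extrapolation bias estimate
and bootstrap SE.

**Kinetics.** Folded fraction vs zero-force incubation time is fitted by
f(t) = A(1 − e^(−t/τ)) (weighted least squares, parametric-bootstrap CI);
a fitted τ below the smallest incubation time is reported as a detection
floor ("τ < 20 ms").

## Worked example

```python
from quadpop import QuadruplexPopulationModel

model = QuadruplexPopulationModel.from_simulation(
    conditions=("transcription", "deaza"), n_curves=1000, seed=42)
results = model.fit(n_boot=1000, seed=42)
print(results.summary())
```

prints

```
Quadruplex population analysis
==================================

Percent formation (% of all F-X curves)
       transcription  deaza
2G-HQ           18.3    0.0
3G-HQ           10.6    0.0
GT               3.8    7.6
GQ              12.5   25.2
none            54.8   67.2

hq_total_transcription                 28.9
gq_gt_total_transcription              16.3
quadruplex_total_transcription         45

rupture-force classes [transcription]: 25.6 pN (n=186), 31.3 pN (n=266)

rupture-force classes [deaza]: 24.4 pN (n=148), 25.7 pN (n=180)

Jarzynski dG_unfold [transcription] (kcal/mol):
  2G-HQ     2.4 +/- 0.1 (bias +0.0, n=183)
  3G-HQ     4.8 +/- 0.1 (bias -0.0, n=111)
  GQ        7.8 +/- 0.1 (bias +0.0, n=125)
  GT        4.7 +/- 0.2 (bias +0.0, n=33)

Jarzynski dG_unfold [deaza] (kcal/mol):
  GQ        7.1 +/- 0.1 (bias +0.0, n=252)
  GT        4.1 +/- 0.1 (bias +0.0, n=76)
```

Read it as: 1000 simulated pulling curves per condition were filtered,
segmented and scanned for ruptures; under regular transcription ~45% of
curves carried a folded structure (54.8% plain duplex/R-loop), dominated by
hybrid quadruplexes (2G-HQ + 3G-HQ = 28.9%), and the ~4 nm population was
split 10.6/3.8 between 3G-HQ and GT using the deaza GT:GQ ratio. The
rupture-force classes separate the stronger hybrid (~31 pN) from the DNA
species (~25 pN), and the per-species ΔG columns give the Jarzynski
estimate, its bootstrap SE, the finite-sample bias estimate and the event
count. With one structure species per curve the folded percentages carry
binomial sampling error (≈ ±1.5% at n = 1000), so run-to-run values move
by a few percent.

A shell pipeline does the same end to end and also writes per-stage
artifacts (events CSV, population JSON, kinetics fits, run manifest):

```
quadpop run --seed 1 --outdir myrun
```

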