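# Methods

## Scope and model

`quadpop` analyses constant-loading-rate optical-tweezers experiments on a
G-rich DNA construct carried by long dsDNA handles, in which at most one
folded species (DNA G-quadruplex GQ, G-triplex GT, or a DNA/RNA hybrid
quadruplex 2G-HQ/3G-HQ) is present per pulling curve. The analysis treats
the tether as an extensible worm-like chain and every unfolding transition
as instantaneous on the sampling timescale. All stages — filtering, event
detection, ΔL measurement, population deconvolution, percent formation,
free energies, folding kinetics — are implemented against this model, and a
generator producing synthetic recordings under the same model provides
ground truth for validation.

## Tether mechanics

The extension-per-contour ratio is r(F) = 1 − ½√(k_BT/(F·P)) + F/S.

| parameter | default | units | rationale |
|---|---|---|---|
| P (handle persistence length) | 50.9 | nm | standard dsDNA value for this construct chemistry |
| S (stretch modulus) | 1168 | pN | idem |
| T | 296.15 | K | experiments at 23 °C; k_BT = 4.0888 pN·nm |
| ℓ (ss contour per nt) | 0.44 | nm/nt | calibrated so ΔL = 1.8/3.8/6.0 nm map to 9/14/19 nt |
| w (folded width) | 2.3 | nm | idem; n = round((ΔL + w)/ℓ) |
| P_ss (ss persistence length) | 1.0 | nm | standard single-strand value (Marko–Siggia interpolation) |

The interpolation formula is accurate above a few pN; the analysis never
evaluates it below 5 pN (fit windows and event acceptance enforce this).
The ΔL→nt constants are a calibration, not a first-principles formula: they
are chosen once so that nearest-integer rounding reproduces the canonical
9/14/19-nt assignments, and exposed in the run configuration
(`ntconv.contour_per_nt_nm`, `ntconv.folded_width_nm`).

The single-strand stretching energy ∫₀^F x(F′)dF′ uses an inextensible WLC
inverted on a dense grid and composite-trapezoid quadrature (1000 steps;
halving the step changes the result by < 0.1%, verified in the tests).

## Synthetic-data generator

Each condition is a prevalence table over {2G-HQ, 3G-HQ, GT, GQ, none} with
a per-species catalog (ΔL mean ± SD, Bell–Evans x‡ and k₀, zero-force
folding τ):

* regular transcription: 17.3 / 9.4 / 3.8 / 12.2 / 57.3 %; ΔL centers
  1.8 ± 0.2, 3.8 ± 0.5 (both middle species), 6.0 ± 0.6 nm
* deaza-GTP transcription: GT 8.1 (3.3 ± 0.4 nm), GQ 25.9 (5.5 ± 0.2 nm),
  none 66.0 %
* no transcription: GT 14.7 (4.2 ± 0.5 nm), GQ 9.6 (6.0 ± 0.6 nm), none 75.7 %
* controls: mutant 2% folded, lithium 6.7%, spacer 7.9% (broad 5.0 ± 1.5 nm
  residual species)

Rupture forces follow Bell–Evans first-passage statistics at the protocol's
loading rate (5.5 pN/s), sampled by exact inverse-CDF. The barrier distance
is x‡ = 4.0 nm for every quadruplex species, giving a rupture-force SD of
k_BT/x‡ · π/√6 ≈ 1.3 pN that matches the observed force-histogram widths;
k₀ is then fixed in closed form so the distribution *mean* is 31 pN for the
hybrid species and 25 pN for GQ/GT (the mode sits γ·k_BT/x‡ ≈ 0.6 pN above
the mean). Any (x‡, k₀) pair reproducing the same histograms would serve;
this one was chosen for that agreement and kept.

Folding kinetics at zero force are single-exponential: τ = 30 ms for the
hybrids, 10 ms for GQ/GT when RNA is present (below the 20 ms force-jump
dead time), 150 ms without transcription. FPP species occupancy after
incubation t is P(s,t) = prevalence_s·(1 − e^(−t/τ_s)), which saturates to
the steady-state table.

Traces are synthesized at 1000 Hz with i.i.d. Gaussian noise (force SD
0.5 pN, extension SD 1.0 nm) on a handle of 1595 nm contour (4718 bp ×
0.338 nm/bp). A rupture appears as an extension jump ΔL·r(F) plus a
transient force drop of 1.8 pN/nm × jump (an effective trap/tether
stiffness) that the feedback re-ramps away with a 60 ms time constant —
large enough to survive 100 Hz filtering, small enough that detection is a
real signal-processing task. Economy choices: F–X ramps turn around at
45 pN (all species rupture well below), the FPP hold at 0 pN is stored as a
5-sample token with the incubation time in an annotation column, and FPP
probe ramps are truncated ~4 pN past the rupture.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real recordings: instrument drift and 1/f noise,
bead/trap hydrodynamics and stiffness miscalibration, tether misalignment
or multiple tethers, refolding during the relax branch, force-dependent
refolding, and any deviation of real quadruplex mechanics from the
one-species-per-curve, instantaneous-rip, Bell–Evans picture. Recovery
results on synthetic data validate the estimator implementations, not the
physics of any particular experiment.

## Trace processing

Savitzky–Golay smoothing (window 11, polyorder 2 at 1000 Hz) followed by
10× decimation to 100 Hz. Detection scans the loading phase for force drops
≥ 1.5 pN within ≤ 3 filtered samples (declared thresholds, set from the
generator's SNR: filtered force noise ≈ 0.23 pN makes 1.5 pN a ≥ 5σ
criterion, keeping the false-event rate per cycle far below the 2% budget
while the smallest real drops, ≈ 3 pN, remain ≥ 10σ).

ΔL is measured twice per event:

* **flanking points**: sample means of the local contour estimate x/r(F)
  over 8 clean filtered samples on each side of the transition (the samples
  adjacent to the jump are excluded because the filter smears across it);
  their difference is the released contour, and Δx = ΔL·r(F_rupture).
  Averaging x/r per sample rather than dividing window means avoids a
  Jensen bias that grows with the drop size.
* **WLC fits**: least-squares contour lengths (linear in L for fixed r) of
  the pre-rupture stretch branch and the relax branch over F ∈ [5 pN,
  F_max − 1 pN]; ΔL is their difference. On noiseless data the two routes
  agree to ≪ 5% (tested); with default noise the flanking route carries
  ≈ 0.3 nm of point noise per event, so the 5% agreement is a property of
  the estimators, not an event filter.

The rupture force is the pre-drop filtered sample's force. Events with ΔL
outside 0.5–10 nm are discarded as artifacts; when several events pass in
one cycle only the largest-ΔL event enters population accounting (one
species per curve) and the rest are logged.

## Population analysis

PoDNano: Gaussian KDE with the pooled-sample Silverman bandwidth, evaluated
by binning (1024 bins) and kernel convolution; bootstrap resamples are
multinomial redraws of the bin counts, which leaves the estimator unchanged
but makes 3000 resamples cheap. Peaks are KDE local maxima above 5% of the
maximum density (the floor rejects isolated-outlier micro-peaks, which
would otherwise appear in ~63% of resamples and fake support); bootstrap
peaks are matched one-to-one (greedy nearest, 1.0 nm radius) and pooled
peaks with < 50% support are dropped. The mixture fit (EM, scikit-learn)
uses k = number of retained peaks, initialized at the peak centers, with a
0.05 nm SD floor on refit of degenerate components; components are reported
mean-sorted. Percent formation uses maximum-posterior assignment, a 4-SD
outlier bucket, and largest-remainder rounding so each condition's
percentages sum to exactly 100.0.

Component→species mapping: means < 2.75 nm are 2G-HQ (GT if no hybrid can
form), < 4.85 nm the 3G-HQ/GT band, larger means GQ. The ~4 nm band is
split arithmetically by the deaza GT:GQ ratio; event-level labels inside
the band are then drawn Bernoulli at the deconvolved fraction (seeded), and
the same split is reused when labelling FPP events.

## Energetics

W_raw = F_rupture·Δx (rectangle work of an instantaneous rip at constant
force) minus the conjugate stretching work of the released strand. The
released contour is the *measured* ΔL (fractional nucleotides allowed)
rather than the rounded nt count times ℓ: the nt conversion adds the folded
width w, which is geometry already present before unfolding, and charging
its stretching energy would over-correct — with it the "correction" exceeds
W_raw for the 9-nt species, which is unphysical for a mechanically stable
fold. Works may still be negative for marginal events and are kept, as the
Jarzynski average requires the full distribution. ΔG uses log-sum-exp; the
bias is mean(dG over 200 seeded half-size subsamples) − dG(n), i.e. the 1/n
extrapolation to infinite sample size; SE is a 200-resample bootstrap SD.
Unit conversion: 1 kcal/mol = 6.9477 pN·nm per molecule (so k_BT(23 °C) =
0.5885 kcal/mol). Absolute ΔG values from synthetic data reflect the
generator's idealized work distribution; only their ordering
(GQ > 3G-HQ > 2G-HQ) is a meaningful cross-check.

## Kinetics

Folded fractions per incubation time with binomial SE (+0.5 continuity
correction at extreme counts); weighted least squares of A(1 − e^(−t/τ))
over (A, log τ) with restarts across τ decades; 95% CI by parametric
bootstrap (binomial redraws at the fitted curve, 200 refits). The default
incubation grid is {0.02, 0.05, 0.1, 0.2, 0.5, 1, 2, 5} s; τ̂ below the
smallest time sets `floor_flag` and is reported as "< 20 ms" — the
force-jump dead time bounds, but cannot time, faster folders. Because the
~4 nm band is split stochastically, the HQ series inherits a ~10%
contamination of fast-folding GT events, which biases the fitted hybrid τ
a few ms low; the bootstrap CI absorbs this at the default design.

## Problem sizes and seeds

Default analyses use 2000 F–X curves per condition, 3000 PoDNano resamples,
and FPP series of 8 incubation times × 500 cycles — sizes at which every
population in the study conditions is sampled with useful precision while a
complete three-condition run with kinetics finishes in a few minutes on one
CPU. Every stochastic stage takes an explicit seed; pipeline stages derive
theirs from the master seed by hashing the stage name, and the run manifest
records all of them, so reports are byte-reproducible.

## Known limitations

* One accepted event per curve: genuine tandem unfolding (two stacked
  2G-HQs) would be folded into the largest event.
* No drift correction or baseline alignment; coordinates are relative to
  the zero-force tether.
* The GT/3G-HQ split is statistical, not per-molecule; species-resolved
  quantities inside the ~4 nm band (ΔG, τ) carry the split's mixing error.
* The Bell–Evans and single-exponential forms are assumed, not selected;
  no Dudko–Hummer–Szabo rate extraction, no multi-exponential kinetics,
  no Crooks/Bennett estimators.
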