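# Methods

This note documents the models, parameters and numerical choices behind
`snfsim`, and what its synthetic-data experiments can and cannot show.

## Synthetic LFP generator

**Baseline.** Each channel is unit-variance 1/f ("pink") noise plus a weak
6 Hz theta oscillation with a slowly varying Gaussian-smoothed envelope,
scaled to a 0.1 mV standard deviation (depth-electrode LFP is mV-scale).
Channels are mutually independent, so inter-hemispheric phase synchrony is
low at baseline, and 30 s block band powers are stationary (coefficient of
variation < 0.25).

**Ictal epochs.** An ictal driver is a spike-wave train — a biphasic 30 ms
spike followed by a 120 ms slow wave, repeated at 5–8 Hz with ~5 ms timing
jitter — plus band-limited Gaussian noise in each analysis band (alpha
8–13, beta 13–30, gamma 30–80 Hz). Component amplitudes are solved in
power space against a fixed-seed reference baseline: the spike train is
capped at 60% of each band's target power `band_gain × baseline`, and band
noise tops each band up exactly, so realized Welch band powers land within
±20% of the target at any synchrony setting. `band_gain ≥ 2` therefore
guarantees detectability under the detector's 2× rule by construction.

**Synchrony control.** The two hippocampal channels are mixtures
`λ·common + √(1−λ²)·independent` of driver realizations; the right channel
may receive a constant phase lag (frequency-domain rotation). λ is solved
by bisection so the realized broad-band (1–48 Hz) phase-locking index over
5 s windows matches the requested target; the λ↦R map is solved once per
parameter set on a canonical fixed-seed realization and cached (the map is
stable across realizations to ~±0.02). Windowed broadband phase-locking has
a floor of R ≈ 0.15–0.2 for fully independent signals (finite-window
Rayleigh statistics with autocorrelated phases), so targets below that
floor realize at the floor; ordering across targets is preserved.

**Artifacts.** Motion/cable transients are common-mode across channels:
a Hann-enveloped offset plus an 8–30 Hz ringing burst, peak 12× baseline
SD, durations 0.2–2 s, Poisson-timed. Identical waveforms on every channel
reflect the common-mode nature of motion artifacts.

**Epoch splicing** uses a 0.5 s raised-cosine cross-fade so junctions never
exceed the 5×SD step bound that would confound the detector.

What this generator does *not* emulate: biophysical seizure dynamics,
electrode drift, state-dependent spectra (sleep/wake), or inter-animal
variability. Detector results on it demonstrate the algorithmic contract,
not in vivo performance.

## Detection

The real-time path is causal: 0.5 Hz second-order Butterworth high-pass
(single-pass; a zero-phase variant exists for offline scoring), 250-sample
frames with 50% overlap, Hann periodogram band powers per frame.

**Band-power statistic.** A raw 0.5 s periodogram has so few degrees of
freedom per band that a 2× threshold would trip constantly on stationary
noise. The detection statistic is therefore a causal trailing average with
a constant time-bandwidth product (default 40) per band: alpha (5 Hz wide)
averages 8 s of frames, beta 2.4 s, gamma 0.8 s — every band's statistic
has ≈80 degrees of freedom, putting the 2× false-alarm tail below one
event per hour while the wide gamma band still crosses within ~2–3 frames
of a gain-3 onset. Trigger rule: OR across bands and channels, threshold
2× the per-channel-band baseline (median of the statistic over the 5 min
baseline window). Event offset is declared after all statistics stay below
threshold for 2 s (the offset-hold; termination latency downstream inherits
this convention). Because the alpha statistic remembers 8 s, scoring allows
a grace period of that length after a true offset before counting triggers
as false positives.

**Chronic mode** re-estimates the baseline with a multiplicative trailing
median tracker (log-step sized to a 10 min horizon), frozen during
detected events, blanking and artifact frames. A trigger additionally
requires spike rate ≥ 3/s and ISI coefficient of variation ≤ 0.6 over the
trailing 2 s (spikes = |x| peaks above 5× MAD with ≥ 50 ms separation); the
gate arms the onset only — persistence is tracked by band power. Artifact
frames (any-channel amplitude above 10× MAD, or rectified-envelope
autocorrelation above 0.8 at 10–80 ms lags on all channels) are excluded
before evaluation, with a one-frame halo. The MAD factors deliberately
separate the generator's spike (≈4–8× SD) and artifact (≥10× SD) regimes.

## Synchrony

Phase is extracted by 4th-order Butterworth band-pass (default broad
1–48 Hz, configurable) followed by the analytic-signal angle; R is the
modulus of the windowed circular mean of phase differences (1 s windows,
0.5 s hop, first/last 0.5 s excluded for filter edges). Absolute R values
depend on the band/window convention; only orderings and threshold
behavior (hyper-synchrony at R ≥ 0.7) are treated as meaningful.

## Field model

**Geometry.** An ellipsoidal brain of 24 × 16 × 12 mm centered at
(AP −3, ML 0, DV −5) mm from bregma contains two curved-slab hippocampi
whose ML/DV centerlines are linear in AP depth, passing through the
implanted electrode coordinates; the slabs occupy ≈3.3% of brain volume
(the rodent range). Default voxel size 0.25 mm.

**Conductivities** (S/m): brain 0.0626, hippocampus 0.0988, electrode
insulation 6.62e-7, air 0; a homogeneous 0.7 S/m variant serves the
heterogeneity experiment. Electrode *metal* is not entered in the stencil:
a stainless-steel conductivity (1.45e6) against tissue would create a
1e7:1 contrast that wrecks conjugate-gradient conditioning with no effect
at this resolution — contacts are current source/sink voxels instead, with
the insulated shaft marked as a low-conductivity column above the tips.

**Solver.** 7-point finite differences with harmonic-mean face
conductances over conducting voxels only (air exclusion realizes the
insulating boundary exactly); Jacobi-preconditioned conjugate gradient to
relative residual 1e-8 (cap 50,000 iterations); gauge fixed by zero-mean
potential. E = −∇V with central differences inside the domain and
one-sided differences at the boundary — differencing into air (where V is
undefined) produces spurious surface fields. Dipole contacts that would
round into a single voxel at coarse resolution are kept distinct by
nudging the anode one voxel dorsal.

**Montages.** SNF: eight vertical bipolar dipoles (cathode at the tip,
anode 0.4 mm dorsal) at the implant coordinates, fired in the order
L1 L2 L3 L4 R4 R3 R2 R1. WF: anterior shafts anode, posterior shafts
cathode per hemisphere (the in vivo polarity assignment within the WF
pairs is not documented; this choice maximizes the along-axis spread that
defines wide-field stimulation). Note that resolving the 0.4 mm tip
spacing requires ≤ 0.25 mm voxels; coarser grids merge the dipole and
underestimate SNF confinement.

**Metrics.** Target coverage is the fraction of hippocampal voxels whose
*sequential* field — the per-voxel maximum of |E| over the eight
sub-fields, since each voxel experiences each sub-pulse in turn — reaches
100 mV/mm. Off-target spread at 10 and 50 mV/mm is the per-sub-configuration
maximum fraction of non-hippocampal brain voxels exceeded (sub-fields at
different time steps do not union spatially). WF/SNF comparisons are made
at currents matched to equal (≥ 90%) target coverage, found by bisection on
the amplitude of the unit solutions (linearity makes re-solving
unnecessary).

**Heterogeneity experiment.** The homogeneous 0.7 S/m solution is compared
with solutions in which every tissue voxel's conductivity is multiplied by
an independent U(0.9, 1.1) factor (insulation and air untouched), over ≥10
seeds, warm-starting each perturbed solve from the homogeneous potential.
The deviation measure is the relative change of the sequential induced
field in the hippocampus, excluding voxels below 1% of the target median
(with the sequential maximum no target voxel is near a null, so nothing is
actually excluded). Measured deviations are 5.6–8.4% over ten seeds.
Voxel-wise relative deviations of a *single* sub-field are dominated by
inter-dipole null regions, where the ratio is physically meaningless.

**Electrode-count sweep.** n = 1..6 vertical dipoles evenly spaced along
one hippocampal centerline; for each n the common amplitude is bisected to
90% union coverage and the off-target fraction at 10 mV/mm evaluated at
that current. Required current and spread decrease with n and plateau past
4 pairs; a ≤2% non-monotone ripple from voxelized dipole placement is
tolerated in the checks.

## Point-neuron thresholds

The membrane is a leaky integrator `τ dV/dt = −V + k·(E·û)` with
τ = 10 ms, threshold 15 mV, coupling k = 0.15 mV per mV/mm, 1 ms
refractory, integrated with the exact exponential update at dt = 10 µs
(10× finer than the 100 µs gaps), realized as an IIR filter restarted at
each spike. The stimulus is the 130 Hz biphasic train (300 µs per phase,
no interphase gap); the SNF drive concatenates the eight sub-field
projections with 100 µs gaps (5.5 ms of a 7.69 ms period), the WF drive is
a single pulse. Thresholds come from bisection on amplitude to 1% (field
linearity rescales the solved maps), validated against the closed-form
strength-duration threshold `V_th / (1 − e^{−PW/τ})` and a 1 µA exhaustive
scan. 18 probe neurons sit ≈0.5 mm under the dorsal surface in a
motor-cortex shell (AP +0.5..+3, |ML| 1–3 mm) with radial orientations.
Only threshold orderings and SNF/WF ratios are claimed (observed ≈2.5–3×
at the default probes); absolute microamp values depend on morphology this
model does not have.

## Closed-loop model

Ictal onsets are Poisson (default 20/h, the dense event rate of an acute
status-epilepticus session); ictal termination is piecewise-exponential
with base hazard 1/30 s⁻¹ (mean 30 s untreated events) multiplied by
`1 + β·dose` while a train is on. The dose is the per-hemisphere
sequential-coverage fraction at the arm's current cap (SNF 0.543 and WF
0.693 at 650 µA, LIWF 0.091 at its 140 µA safety cap on the default
geometry), summed over stimulated hemispheres; randomizing the SNF order
multiplies the effective dose by a coherence factor 0.3 (a free parameter
standing in for the observation that an unorchestrated sequence fails to
summate). β = 6 makes the bilateral SNF arm terminate ≈75–80% of events
within 10 s of the first train — the anchor for "termination success".
Detection gates stimulation: each onset is rendered as LFP and detected
(acute: repeated 5 s trains with 10 s non-stimulation intervals while the
event persists; chronic: one train then a 100 s lockout), with the
detector blanked during trains. Event durations are drawn by inverting the
cumulative hazard of the realized schedule; events are censored at 600 s
or session end.

The hazard-multiplier recovery estimator is the ratio of exponential-rate
MLEs (terminations per exposure time, stim-on vs stim-off strata, censored
events contributing exposure only). Its log-scale standard error is
`sqrt(1/n_on + 1/n_off)`, minimized when the strata carry equal hazard
weight; the recovery harness therefore uses a 15 s inter-train interval
(3× multiplier × 5 s trains balances 15 s gaps), giving σ ≈ 0.093 at 500
events so that [2.5, 3.6] is the estimator's ≈95% interval around a true
multiplier of 3. The protocol's 10 s refractory is kept everywhere else.
The acceptance test verifies the 95% claim with an exact binomial test
over 20 fixed seeds rather than demanding 19/20, which would reject a
true 95% estimator one run in four. Arm
orderings (SNF < LIWF < non-stim percent time in seizure, bilateral <
unilateral, ordered < random SNF) are model consequences of the dose and
coherence definitions, checked as one-sided rank-sum dominance over 6
sessions of 3 h; they mirror the in vivo orderings but are not independent
evidence about biology.

## Problem sizes and defaults in tests

Unit tests run the field solver at 0.5 mm and the experiments at
0.25–0.4 mm; heterogeneity uses 10 seeds at 0.25 mm; detector contracts
use 1 h records; recovery uses 20 seeds × 500 events. These sizes were
chosen so the full chain remains a desk-scale computation.

## Known limitations

* The generator's amplitudes are calibrated to the detector's 2× rule, not
  to animal data; absolute R values are convention-dependent.
* The parametric geometry reproduces scale and topology, not anatomy;
  coverage fractions and required currents are geometry-dependent and only
  orderings are robust claims.
* The point neuron has no morphology, so threshold magnitudes (and the
  in vivo 650/140 µA safety caps) are not reproduced — only WF/SNF ratios.
* The seizure-state model is phenomenological; its hazard parameters are
  free choices anchored to qualitative termination behavior.
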