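# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the limitations a user should keep in mind.

## Containers and units

Spike times and stimulus onsets are seconds; peri-stimulus quantities
(latencies, ISIs, bin widths) are reported in milliseconds. Voltages are mV,
currents pA, resistances MΩ, capacitances pF, conductances nS. With these
units C_m [pF] = 1000·τ[ms]/R_m[MΩ] and g[nS] = I[pA]/V[mV] without further
conversion factors.

## Synthetic data

The generators are phenomenological templates, not biophysical simulations:
they reproduce the *measured feature set* of each signal class so that the
matching analysis stage can be validated by round trip.

* **Soma sizes** — Gaussian mixtures truncated at 0 µm (negative draws are
  resampled; negligible mass for realistic parameters). Defaults follow the
  two-population GABAergic distribution (peaks 11.9 and 16.2 µm, SDs 1.3 and
  2.0 µm).
* **Spontaneous trains** — gamma-renewal ISIs (shape 1/CV², default CV 0.5).
  The gamma law is a stand-in: the real recordings state only summary rates
  and irregularity bounds, so absolute ISI-entropy values should not be
  compared across studies (see classification below).
* **Stimulus-locked inhibition** — inhomogeneous Poisson by thinning, with
  the rate switched to the inhibited value inside a window of fixed onset
  and duration after each light pulse (defaults 10.9 → 1.58 Hz, 14.5 ms
  onset, 23.4 ms duration). Real inhibition has graded onsets and
  trial-to-trial latency jitter; a green detection test therefore
  establishes the detector's behaviour under the idealized rate-step model
  only.
* **AP traces** — piecewise-analytic waveform: linear pre-threshold ramp,
  linear upstroke (half the half-width, snapped to the sample grid so the
  peak falls on a sample), exponential repolarization whose asymptote and
  time constant are solved (Brent) so the half-width and AHP time are met
  exactly, then a linear inter-spike recovery to threshold. Features that
  are integer multiples of the sample period round-trip exactly; otherwise
  within one sample period.
* **IPSCs** — a sin² rise scaled to the requested 10–90% time joined at the
  peak to an exactly bi-exponential decay, plus white Gaussian noise. A
  difference-of-exponentials product would contaminate the decay segment
  with the rise time constant and break noiseless round-trip identity; the
  piecewise form keeps the decay pure by construction.
* **Membrane steps** — single-exponential charging with τ = R·C toward
  ΔV = I·R.
* **Intensity tables** — two bivariate-Gaussian populations in
  (eGFP, neurogranin), 25% low-eGFP by default with ~5 within-population
  SDs of eGFP separation, and zero-inflated Poisson apposition counts per
  population (GABAergic: 41% contacted, mean 7.65 among contacted;
  glycinergic: 3.4%, mean 1.88).
* **Extracellular traces** — a Gaussian-derivative biphasic template
  (~1 ms) at each spike time in white noise; no waveform variability or
  overlap, so detection tests certify thresholding, not sorting.

All generators take explicit integer seeds; fixed seed ⇒ bit-identical
output. The pipeline driver derives per-stage seeds from one pipeline seed
by fixed offsets.

## Morphometry

Histograms use 1-µm bins by default (configurable). The k-component model
Σ aᵢ·exp(−(x−µᵢ)²/2σᵢ²) is fitted to the bin counts by bounded nonlinear
least squares (deterministic initialization: k-quantile means, pooled SD,
peak-count amplitude), R² is computed against the counts, and 95% CIs of the
means come from the fit covariance. This is deliberately a *binned* fit, not
an EM mixture fit, matching how such histograms are usually quantified;
fits are unweighted (whether bin-count weighting was used upstream is
unknowable from a figure).

Model selection (1 vs 2 components) uses an extra-sum-of-squares F-test at
α = 0.01 for the three extra parameters, and additionally requires both
components to carry ≥ 10% of fitted mass and the peak separation to exceed
the larger component SD. Adjusted R² alone proved too permissive: on
118-sample unimodal histograms the two-component fit wins adjusted R² by
absorbing bin noise. Measured over 30 seeds per scenario the F-test
criterion selects k = 1 on unimodal samples (n = 118: 28/30; n = 193:
29/30) and k = 2 on the bimodal population (n = 650: 30/30).

## Intracellular

* **AP threshold** — voltage at the main (largest) maximum of the second
  derivative within 2 ms before the AP peak; the first derivative is
  low-pass filtered at 1 kHz with a zero-phase Butterworth before the second
  difference, which smooths noise without biasing corner locations.
* **AHP** — minimum within 10 ms after the peak or until the next spike,
  whichever comes first; AHP time is measured from the threshold time.
* **Half-width** — duration at threshold + amplitude/2, crossings found by
  linear interpolation between samples.
* **Grand average** — peak-aligned mean waveform (−3 to +10 ms), features
  re-extracted from the average.
* **Passive properties** — single-exponential fit of the step response;
  R_m = ΔV/I, C_m = τ/R_m (the dimensionally consistent reading of
  "ratio of R_m and τ"). Fits with r² < 0.9 are flagged, not discarded.
* **Accommodation** — steady-state index = mean instantaneous rate of ISIs
  ending in the last 200 ms of the step divided by the mean rate of the
  first two ISIs; windows are configurable because only the concept, not
  the windows, is standard.
* **ISI prolongation** — control ISI = mean of stimulus-free ISIs;
  stimulated ISI = mean of ISIs containing ≥ 1 light onset; increase
  normalized by the control.
* **Time locking** — across-trial V_m SD timecourse, smoothed with a 5-ms
  moving average, normalized to the pre-stimulus mean; the post-stimulus
  decrease is z-scored against the baseline variability of the smoothed SD
  and significant at z ≥ 3 (inclusive). The smoothing window is what keeps
  the null false-positive rate of the max-over-window statistic below 5%
  (~20 effective comparisons instead of ~1000).
* **IPSC kinetics** — amplitude baseline-to-peak; 10–90% rise by linear
  interpolation; decay fitted from the peak with A(f·e^(−t/τ₁) +
  (1−f)·e^(−t/τ₂)), bounded, initialized from the 1/e crossing, components
  sorted fast/slow after fitting. A low-SNR flag compares a 0.5-ms-smoothed
  peak against 3 baseline SDs (the raw extremum of pure noise already sits
  ~3 SD up, so smoothing is required for the flag to mean anything).
* **GHK** — anion GHK flux with outward-positive sign convention; the
  reversal is found as a numeric root of the summed Cl⁻ + HCO₃⁻ current in
  [−150, 50] mV (the closed-form anion Goldman equation serves as an
  independent cross-check in the tests). Ionic concentrations ship as an
  editable `IonConfig`; the defaults (Cl 5.2 / 133.5 mM, HCO₃ 16 / 24.8 mM
  in/out, 33 °C) are **calibrated** so that the default permeability ratio
  P_HCO₃/P_Cl = 0.2 gives E_rev ≈ −74 mV. The chord conductance is
  I/(V_hold − E_rev); the slope conductance is the analytic dI/dV of the
  GHK I–V with the permeability scaled to the measured amplitude; the
  symmetric-chloride equivalent applies the same permeability with chloride
  symmetric at the external concentration and bicarbonate omitted, as in
  symmetric-chloride recordings (at symmetric concentrations the GHK I–V is
  exactly linear, so chord = slope there).

## In vivo

Spike extraction: zero-phase Butterworth high-pass (1 kHz, order 4),
absolute-value thresholding at a multiple (default 5) of the MAD-based
noise SD, peak assignment within a 1-ms refractory lockout.

Unit statistics: MSF = count/duration; LCV = SD(ln ISI)/|mean(ln ISI)| with
ISIs in ms (the LCV value depends on this unit convention — documented
because the upstream criteria do not state it); ISI entropy in bits over 50
log-spaced bins from 1 ms to 10 s. The bin layout is a calibration
constant chosen so canonical Golgi-like gamma trains (≈9 Hz, CV 0.5 →
ENT ≈ 3.5 bits, LCV ≈ 0.11) fall inside the classification bounds
(MSF < 20 Hz, 0.5 < ENT < 7.5, 0.02 < LCV < 0.25, all strict). Absolute
ENT/LCV values are therefore not comparable across implementations with
different binning. Units failing the Golgi bounds are labeled "purkinje"
when MSF ≥ 40 Hz (a heuristic; the source criteria are richer) and
"other" otherwise.

PSTHs pool spike counts over pulses into bins anchored at light onset
(latencies then quantize cleanly). Responder detection z-scores each bin
against the baseline bins' mean and SD; a unit is responsive when ≥ 2 bins
with |Z| > 2.5 lie inside the 50-ms post-onset window (bins counted only
when fully contained). The default baseline is the 200 ms before each pulse:
a 100-ms baseline (33 bins) estimates the SD too noisily, which both misses
the canonical inhibition scenario (expected inhibited-bin Z ≈ −3.1 sits
close to the 2.5 criterion) and inflates the null false-positive rate above
5%; with 66 baseline bins the detector reaches ~100% power at 400 trials
with a ~3% false-positive rate (200-seed Monte Carlo). Onset latency is the
start of the first significant bin, peak latency the center of the
maximal-|Z| bin, duration the summed significant time, and the inhibited
rate the pooled rate over the significant bins whose sign matches the net
significant modulation (an isolated spuriously-high bin must not
contaminate an inhibition estimate). Note the inhibited-rate estimator
conditions on significance and therefore carries sampling noise of
~±0.45 Hz at 400 trials; duration is floored near 21 ms for a 23.4-ms
window because only fully-covered 3-ms bins can reach significance.

Smoothed population PSTHs convolve 1-ms-bin counts with a Gaussian kernel
(σ = 3 ms) using reflection padding — the one boundary mode that conserves
the total count exactly — and divide by the mean rate.

## Bursts

A burst is the maximal spike run starting within 20 ms of a light onset
whose consecutive ISIs stay ≤ 10 ms (both configurable); intra-burst
frequency is (n−1)/duration, undefined (NaN) for single spikes — the mean
of 1/ISI is a documented alternative the field sometimes uses.
Stimulus–response curves fit a 3-parameter Hill function to per-level means,
chosen for robustness at the 4–6 stimulus levels typical of such
experiments; constant data short-circuit to a zero-slope plateau.

## Imaging

Channel normalization fits a line to ln(counts) of the intensity histogram
tail above the 80% quantile (64 linear bins) and divides the channel by
−1/slope. For an exponential intensity law with decay λ the fitted slope is
−λ exactly in expectation, which pins the reading of "slope of the fit to
the logarithmic distribution": it makes the procedure gain-invariant and
idempotent. Linear (not logarithmic) bin spacing is what makes the
exponential-recovery identity exact; this is the one deliberate departure
from the original one-line description, and it is test-pinned.

Cell typing runs 2-means on (eGFP, neurogranin) with deterministic
farthest-point seeding plus seeded k-means++ restarts (lower inertia wins);
on tables of ≤ 12 cells the result matches exhaustive minimization of the
2-means objective. The lower-eGFP cluster is labeled GABAergic. A cell is
"contacted" at ≥ 1 apposition; contact summaries conserve totals by
construction. Printed-count arithmetic (e.g. 245 appositions on 32 of 79
GABAergic cells → 7.65 per contacted cell, 32/40 = 80% of contacted cells
GABAergic) is reproduced by `contact_summary` on tables built from those
counts; the "97% of terminals" summary statement found in some figure
legends is inconsistent with the printed counts (245/260 = 94.2%) and is
not used anywhere.

## Known limitations

* No conductance-based simulation, no raw image synthesis, no spike
  sorting, no liquid-junction or series-resistance corrections.
* The gamma-renewal stand-in for spontaneous trains and the calibrated
  ENT/LCV binning mean classification thresholds transfer to real data only
  after re-calibration.
* The GHK solution composition is calibrated, not derived from a published
  recipe; users with exact solution tables should edit `IonConfig`.
* The inhibited-rate and duration estimators inherit 3-ms bin quantization
  and significance-conditioning noise; at 400 trials expect ±0.45 Hz and
  ±3 ms seed-to-seed scatter.
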