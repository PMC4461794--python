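# cerephys

Quantitative analysis of the inhibitory nucleo-cortical (iNC) pathway of the
cerebellum — the projection from mixed GABA-glycinergic cerebellar-nuclei
neurons back onto Golgi cells of the granule-cell layer. The package
re-implements, as a tested and reusable library, the analysis stages such a
circuit-mapping study needs, together with a synthetic-data generator so that
every stage can be exercised and validated without any recorded data.

It is aimed at cellular neurophysiologists who want reproducible, scriptable
versions of the standard in-vitro / in-vivo measurement pipeline:

* **Morphometry** — one- and two-component Gaussian fits to binned soma-size
  histograms (peaks, confidence intervals, R²), model selection between them,
  and two-sample Kolmogorov–Smirnov comparisons.
* **Intracellular** — AP waveform features (threshold at the main peak of the
  second voltage derivative, half-width, AHP minimum/time), passive membrane
  properties (R_m, τ, C_m = τ/R_m from current-step fits), capacitance-
  normalized I–F curves, spike-frequency accommodation, ISI prolongation by
  optogenetic stimuli, across-trial spike time locking, IPSC kinetics (10–90%
  rise, bi-exponential decay) and pharmacological block, and
  Goldman–Hodgkin–Katz conversion of IPSC amplitudes into reversal potentials
  and chord/slope/symmetric-chloride conductances for mixed Cl⁻/HCO₃⁻
  channels.
* **In vivo** — Butterworth high-pass filtering and threshold spike
  extraction, unit classification from ISI statistics (MSF, log-ISI CV,
  ISI entropy), and PSTH Z-score responder detection: a unit is modulated
  when |Z| > 2.5 in at least two 3-ms bins within 50 ms of light onset; the
  significant time defines the inhibition duration, and onset/peak latencies
  are measured from light onset.
* **Burst** — spikes-per-burst, intra-burst frequency (n−1)/duration and
  burst duration of optogenetically evoked bursts, plus saturating
  (Hill-type) stimulus–response fits.
* **Imaging** — per-channel normalization of soma fluorescence intensities
  from the log-histogram slope, 2-D k-means separation of GlyT2-eGFP /
  neurogranin intensities into GABAergic vs glycinergic Golgi-cell
  populations, and apposition-count contact summaries.

The fit-shaped analyses are scikit-learn-style estimators
(`GaussianHistogramModel`, `PassiveMembraneFit`, `IPSCKineticsFit`,
`TwoPopulationKMeans`) with `fit`/`get_params` and trailing-underscore fitted
attributes; the module-level functions are thin wrappers over them.

## Worked example

Run the bundled simulate → analyze pipeline (all inputs synthetic, seeded):

```bash
cerephys run --seed 1
```

Among the report's stages (seed-derived numbers, reproduced exactly on rerun):

```json
"invivo_psth": {"responsive": true, "onset_latency_ms": 15.0,
                "duration_ms": 12.0, "baseline_rate_hz": 10.08,
                "inhibited_rate_hz": 1.46},
"ipsc":        {"amplitude_pa": 44.97, "rise_10_90_ms": 2.85,
                "tau1_ms": 8.11, "frac1": 0.54, "tau2_ms": 35.28,
                "fit_r2": 0.92}
```

The in-vivo stage simulated a Golgi-like unit firing at 10.9 Hz whose rate
drops to 1.58 Hz for 23.4 ms starting 14.5 ms after each of 400 light pulses;
the Z-score detector flags it as responsive, locates the onset in the first
significant 3-ms bin (15 ms) and estimates the suppressed firing rate
(1.46 Hz here). The IPSC stage synthesized a 40-pA averaged current with
2-pA noise and recovered its fast/slow decay constants (8.11 / 35.28 ms vs
the generating 8.2 / 34.8 ms).

Equivalent one-shot subcommands exist for each stage
(`cerephys simulate …`, `analyze-ap`, `analyze-passive`, `analyze-ipsc`,
`analyze-isi`, `analyze-psth`, `classify-units`, `analyze-bursts`,
`cluster-intensity`, `fit-morphometry`), all reading the documented CSV /
flat-trace formats and emitting JSON.

## Acceptance script

`scripts/acceptance.py` regenerates, from scratch and from the given seed,
the package's headline quantities: the chord-conductance worked example, the
soma-size sample mean and two-Gaussian peak recovery, the detected inhibited
firing rate of the simulated in-vivo responder, the fast IPSC decay constant
at realistic noise, the k-means GABAergic cell fraction, and the mean ISI
prolongation across 15 simulated cells. Run it from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the models, conventions, calibrated constants and
known limitations.
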