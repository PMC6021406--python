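# Methods

This note documents the models and procedures implemented in
`spikepatterns`, the parameters that matter, and the choices made where the
underlying analysis left the design open.

## Spike-train model and containers

A `SpikeTrain` is one sorted unit's spike times (seconds, strictly
ascending) inside an explicit observation window `[t_start, t_stop]`.
Exact duplicate times — a common artifact of threshold-based spike
extraction — are collapsed on ingest with a logged warning. All interval
statistics derive from successive differences (ISIs); no binning is
involved anywhere except in the autocorrelogram and the burst-threshold
histogram.

## Burst detection

A burst is a **maximal run** of consecutive spikes whose successive ISIs
are all at or below a grouping threshold (`max_intra_burst_isi`), with at
least `min_spikes_per_burst = 2` spikes (fast-bursting dorsal-horn units
commonly fire duplets, so two spikes must qualify). An ISI exactly equal
to the threshold joins the burst. This single-interval operator is the
simplest grouping rule consistent with the burst shapes being described;
no Poisson-surprise or multi-threshold detector is provided.

**Automatic threshold.** When the threshold is `"auto"` (the default) it is
derived per train from the log10-ISI histogram (25 bins over the observed
range, smoothed with a 3-bin moving average). Every interior bin is scanned
as a candidate split point; a split is valid when each side holds a
smoothed peak of at least 2 counts and the bin's own smoothed count is at
most half the smaller side maximum. The deepest valid valley (ties: the
median tied bin) becomes the threshold, back-transformed from its bin
centre. If no valid split exists — including trains whose log-ISI spread is
below 0.05 decades, i.e. near-periodic — the train is declared
burst-free. The half-depth requirement is what keeps unimodal but noisy
ISI histograms (gamma-renewal simple patterns) from acquiring a spurious
threshold; a naive "two largest local maxima" rule fails there. At least
10 ISIs are required.

**Burst statistics.** Instantaneous frequencies are means of *reciprocals*
of intervals, not reciprocals of means: intra-burst over all within-burst
ISIs pooled across bursts (so long bursts weigh more), inter-burst over
the offset-to-onset gaps between consecutive bursts. Onset-to-onset
intervals — a different quantity — feed the regularity CV below. With no
bursts all burst statistics are NaN, never zero.

## Classification

The pipeline (all thresholds in `ClassifierConfig`):

1. Fewer than `min_spikes_for_classification = 10` spikes → `INSUFFICIENT`.
2. Detect bursts; burst-spike fraction ≥ `burst_fraction_threshold = 0.25`
   → bursting, else simple. The boundary (exactly 25%) is bursting.
3. Bursting subtype: **mixed** when, among bursts with ≥ 6 spikes, a strict
   majority shows a decaying intra-burst profile — mean instantaneous
   frequency of the first third of the burst's ISIs at or above
   `fast_slow_limit = 70` Hz while the last third is below it, or a
   first/last-third ratio ≥ `mixed_ratio_threshold = 4`. Otherwise **fast**
   when the pooled intra-burst instantaneous frequency is ≥ 70 Hz (the
   boundary counts as fast), else **slow**. The first-third/last-third
   operationalisation and the 70 Hz boundary assignment are package
   decisions; the source analysis states only a qualitative decay and "a
   limit" at 70 Hz.
4. Regularity: simple patterns use the CV (sample SD / mean) of all ISIs;
   bursting patterns the CV of burst onset-to-onset intervals, requiring at
   least `min_burst_onset_intervals = 3` intervals. CV < 0.5 → prefix R,
   otherwise I; exactly 0.5 is irregular ("under 0.5" is strict). A
   bursting train with too few bursts cannot demonstrate regularity and
   defaults to I with `insufficient_regularity = True`.

`RMB` is an admissible label even though no such cell has been reported:
the classifier does not hard-code an empirical absence.

The classifier is deterministic and CV-based quantities are invariant to a
uniform rescaling of the time axis.

## Pharmacological epochs

`assess_drug_effect` compares the **last** `analysis_window = 300` s of the
control epoch with the last 300 s of the drug epoch (mirroring the
protocol of measuring 5 min before drug onset and the last 5 min of
perfusion). A unit is *inhibited* when post/pre frequency ≤ 0.20
(boundary inclusive); *regularised* when the pre-label is irregular and
the post-label regular. A unit silent in the control window is "not
assessable" — never inhibited by zero division — and is excluded from
contingency tables with a warning.

`chi_square_2x2` is the Pearson chi-square without continuity correction
(1 df). The uncorrected form is the default reading of "Chi-square test";
with the margins of the published tables the conclusion is
correction-invariant.

**Percent formatting.** The class-distribution report rounds percentages
half-up to one decimal; the inhibition tables truncate (floor), which is
the only rule reproducing the published strings (8/45 → 17.7%,
22/24 → 91%). The published tables are not perfectly self-consistent on
this point (one entry reads 20.6% where truncation gives 20.5%); the
package applies floor uniformly.

## Membrane currents

* `measure_ih`: instantaneous current = mean over 5–15 ms after step onset
  (past the capacitive transient), steady state = mean over the final
  100 ms of the 1.5 s step. The windows are package choices; the source
  names the quantities but not the windows. Amplitude is the absolute
  steady-minus-instantaneous difference; the signed difference is kept
  because the sign convention is ambiguous. Density is current per
  picofarad (pA/pF), conventionally at the −132 mV step.
* `isolate_persistent_current`: pointwise control − blocked ramp current,
  paired with the junction-corrected ramp voltage (offset 11.5 mV,
  configurable). Ramp rate defaults to 26 mV/s, configurable down to
  8 mV/s.
* Conductance transform: g = I/(V − ENa) with ENa = 56 mV; points within
  1 mV of ENa are refused (the transform is singular there).
* `fit_boltzmann`: four-parameter least-squares fit of
  g/gmax = Bottom + (Top − Bottom)/(1 + exp((V50 − V)/Slope)), normalised
  by the **maximum measured** conductance (not a fitted asymptote).
  Initialisation from the data (half-range crossing for V50, 20–80% span
  / 4 for the slope, extremes for Top/Bottom); Slope is bounded positive;
  non-convergence raises `FitError` with the initial guess in the message.

## Synthetic data

The generators state the world the tests run in:

* **Simple patterns** are gamma-renewal processes, shape k = 1/CV², chosen
  because its two parameters map directly onto a (rate, CV) description.
  No claim is made that real neurons are gamma processes. Defaults: IS
  1.16 Hz / CV 1.0, RS 5.62 Hz / CV 0.28.
* **Burst patterns** place bursts sequentially: each onset-to-onset
  interval is the previous burst's duration plus a gamma gap (CV 0.3 for
  regular classes, 1.2 for irregular, so the realised onset CV lands
  clearly on the correct side of 0.5); gaps shorter than 5× the longest
  nominal intra-burst ISI are redrawn (≤ 100 attempts) to keep bursts
  separable. Intra-burst ISIs carry 10% multiplicative jitter. Defaults
  per class follow the published regimes (fast bursts 2–4 spikes near
  124–138 Hz, slow bursts ~28–33 spikes near 13–15 Hz, mixed bursts
  decaying geometrically 120 → 10 Hz — the simplest monotone profile
  matching "high at the start, low at the end").
* **Suites** spawn one substream per train from a master seed
  (`numpy` `SeedSequence`), with per-train parameters drawn within
  ±15–30% of the class regime, so results are reproducible item by item.
* **Drug modulation** thins post-onset spikes to 12% (inhibition) or
  replaces the post-onset segment with a CV-0.25 renewal train at the
  pre-onset rate (regularisation).
* **Voltage-clamp traces**: the I_h step is leak + A·(1 − e^(−t/τ)) with
  τ = 0.3 s; the ramp pair injects a Boltzmann-shaped persistent inward
  current (V50 −51.7 mV, slope 6 mV by default) into the control trace
  only. Synthetic activation points default to the full junction-corrected
  ramp range (−124.5 to −42.5 mV) at 0.25 mV spacing — a conservative
  decimation of a digitized 26 mV/s ramp. This density matters: with only
  ~25 points the free upper asymptote (the ramp tops out at ~82%
  activation) inflates the V50 standard error to ~0.9 mV, and ±1 mV
  recovery cannot be guaranteed; at ramp density the error is ~0.2 mV.

What a green test does **not** establish: the generators sample class
parameters independently (real inter-class correlations are unknown), burst
trains contain no background lone spikes, no bursty drift or
non-stationarity is modelled, and no synaptic coupling between units
exists. Classifier recovery on this suite therefore measures the internal
consistency of the taxonomy's operational definitions, not performance on
recorded data. Likewise the published population summaries (mean class
frequencies, current densities, fraction of current blocked by a drug)
depend on real cells and are not reproduction targets.

## Numerical notes

* CV uses the sample standard deviation (ddof = 1).
* Autocorrelogram: ordered pairs with lag in (0, max_lag], left-closed
  bins of `bin_width` (default 10 ms, max lag 10 s — covering both fast-
  and slow-burst periodicities); zero-lag self-pairs excluded.
* Percent strings are computed in decimal arithmetic, so 49.865% rounds to
  49.9% without binary-float surprises.
* `mean_frequency` counts spikes in the closed window [start, end].
* All randomness flows through `numpy.random.Generator`; every public
  generator accepts a seed, a `SeedSequence`, or a `Generator`.

## Known limitations

* The burst-threshold heuristic assumes at most two meaningful ISI modes;
  multi-scale bursting (bursts of bursts) is not handled.
* Bursting trains with 2-spike bursts give the intra-burst CV from pooled
  single ISIs across bursts, mixing within- and between-burst variability.
* The junction-potential correction is a constant offset; series-resistance
  errors are not modelled.
* Reports assume one label per unit per window; label drift within a
  window is invisible.
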