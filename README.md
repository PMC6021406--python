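# spikepatterns

Classification and pharmacological analysis of spontaneous spike trains
from superficial dorsal-horn recordings (or any sorted extracellular
units), plus voltage-clamp quantification of the two currents implicated
in endogenous rhythmicity: the hyperpolarisation-activated current (I_h)
and the persistent sodium current (I_NaP).

The package is for electrophysiologists who have sorted spike times (e.g.
from a multielectrode array) and want a reproducible, fully scriptable
version of the classic semi-automatic workflow: burst detection,
regularity quantification by the coefficient of variation of inter-spike
intervals, firing-pattern taxonomy, drug-epoch inhibition analysis with
contingency testing, and Boltzmann activation fits.

## The model in brief

* **Regularity.** CV = SD(intervals)/mean(intervals). A pattern is
  *regular* when CV < 0.5 — computed over all ISIs for simple (single
  spike) patterns, and over burst onset-to-onset intervals for bursting
  patterns.
* **Bursting.** A unit is *bursting* when ≥ 25% of its spikes fall in
  bursts — maximal runs of spikes with all ISIs below a grouping threshold
  (chosen automatically from the valley of the log-ISI histogram, or set
  explicitly). Bursts are *fast* or *slow* according to whether the mean
  intra-burst instantaneous frequency (mean of 1/ISI) is ≥ 70 Hz, and
  *mixed* when the frequency decays from above to well below that limit
  within bursts.
* **Taxonomy.** The two axes combine into IS, IFB, ISB, IMB (irregular
  simple / fast / slow / mixed burst) and RS, RFB, RSB (+ RMB admissible).
* **Pharmacology.** A unit is *inhibited* by a drug epoch when its firing
  rate over the last 5 min of perfusion drops to ≤ 20% of the 5-min
  control rate; group differences are tested with Pearson's chi-square on
  2×2 tables.
* **Currents.** I_h = |steady-state − instantaneous| current of a
  hyperpolarising step; I_NaP is the control-minus-blocked ramp current,
  converted to conductance via g = I/(V − ENa), ENa = 56 mV, and fitted
  with g/gmax = Bottom + (Top − Bottom)/(1 + exp((V50 − V)/Slope)).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import spikepatterns as sp

# a regular-simple unit: gamma-renewal train, 5.62 Hz, CV 0.28
train = sp.generate_renewal_train(5.62, 0.28, 300.0, seed=42, unit_id="dh_unit_7")
res = sp.classify_pattern(train)
print(f"{res.unit_id}: {res.label}  rate={res.mean_frequency:.2f} Hz  "
      f"CV={res.cv_classification:.2f}")

# an irregular fast-burst unit: duplet/triplet bursts at ~124 Hz
spec = sp.SyntheticSpec(label="IFB", burst_rate=0.33, spikes_per_burst=(2, 4),
                        intra_burst_freq=124.0, duration=300.0, seed=42)
res = sp.classify_pattern(sp.generate_burst_train(spec))
print(f"{res.unit_id}: {res.label}  onset CV={res.cv_classification:.2f}  "
      f"intra={res.intra_burst_freq:.1f} Hz")

# inhibition contingency: 98/108 irregular vs 8/45 regular units inhibited
chi = sp.chi_square_2x2(sp.ContingencyTable2x2(98, 10, 8, 37))
print(f"chi2={chi.statistic:.2f}, p={chi.p_value:.2e}")
```

prints

```
dh_unit_7: RS  rate=5.61 Hz  CV=0.28
IFB_synth: IFB  onset CV=1.21  intra=124.6 Hz
chi2=79.46, p=4.93e-19
```

The first unit fires at 5.61 Hz with an ISI CV of 0.28 — below the 0.5
criterion, no bursts — so it is a Regular Simple cell. The second groups
essentially all spikes into ~124 Hz bursts whose onsets are irregular
(onset CV 1.21): an Irregular Fast Burst cell. The chi-square on the 2×2
inhibition table shows irregular units are inhibited by synaptic blockade
far more often than regular ones (p ≪ 0.0001).

## Command line

```sh
spikepatterns simulate -c all --duration 300 --seed 1 --out spikes.csv --labels-out labels.csv
spikepatterns classify spikes.csv --out report.csv
spikepatterns classify spikes.csv --epochs epochs.json --out report.csv   # + drug effects
spikepatterns contingency --table 98,10,8,37
spikepatterns autocorr spikes.csv --out acg.csv
```

Spike tables are plain CSV (`unit_id,spike_time_s`, optional
`# t_start=`/`# t_stop=` header); epochs are JSON
`[{"name", "start_s", "end_s", "drugs": []}]`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch under the given seed:
it generates a labelled synthetic suite and classifies it, runs the
drug-epoch inhibition pipeline on modulated trains through the contingency
test, and fits a Boltzmann activation curve from a synthetic ramp pair,
writing the results file at the end.
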