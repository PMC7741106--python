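# paleoproxy

Simulation toolkit for asking what summed probability distributions (SPDs)
of radiocarbon dates can — and cannot — recover about the "true" population
dynamics of hunter–gatherers.

The package:

* simulates **true population trajectories**: an annual consumer–resource
  map whose attractor is a stable limit cycle (50–100-year wavelength,
  growth-phase rates of roughly 0.4–3 %/yr, long-term mean proportional to
  environmental productivity), a stochastic catastrophe model with local
  extinctions every few hundred years, and synthetic annual tax-record
  observations with crashes and record gaps;
* **forward-models trajectories into SPDs**: weighted calendar-date
  sampling, back-calibration through a calibration curve, truncated-normal
  laboratory errors (μ=50, σ=15, bounds 20–80 ¹⁴C yr), recalibration and
  summation, with an optional taphonomic correction;
* estimates **growth rates** three ways: the point formula
  r = ln(N_t/N_0)/t, log-linear exponential fits, and trough-to-peak
  growth-phase segment rates;
* quantifies time-scale-resolved similarity between truth and proxy with
  **wavelet coherence** (Morlet CWT, cone of influence, Monte-Carlo
  significance against AR(1) or white-noise surrogates);
* orchestrates the whole argument as reproducible **pipeline experiments**
  with seeded replicates, JSON reports and CSV side tables.

The headline result reproduced by the default experiment: an SPD built from
5000 dates over 10,000–5,881 cal BP tracks the ~1000-year regime-shift
structure of the underlying population (wavelet-coherence significance
peaks there) but is blind to the 50–100-year cycles; its whole-range
exponential rate (~0.06–0.1 %/yr) is an order of magnitude below the true
within-cycle growth rates (~2 %/yr).

## CLI

```sh
paleoproxy calibrate --c14-age 5000 --lab-error 40 --curve identity
paleoproxy uncalibrate --cal-year 5000 --seed 1
paleoproxy spd --dates dates.csv --normalize --taph-correct
paleoproxy forward-spd --trajectory traj.csv --n 5000 --range 10000:5881 --seed 1
paleoproxy growth-rate --series spd.csv --method expfit --interval 10000:5881
paleoproxy coherence --x truth.csv --y spd.csv --nsim 100 --seed 1
paleoproxy run-experiment --config exp.yaml --out report.json
paleoproxy run-contrast --seed 1
paleoproxy run-taxrecords --seed 1
```

`--curve` accepts `identity`, `wiggly` (a deterministic synthetic curve with
realistic centennial wiggles; the pipeline default) or a path to an
IntCal-format `.14c` file. Exit codes: 0 ok, 2 config error, 3 stage
failure.

## Layout

```
src/paleoproxy/
  synthetic_population.py   population trajectories and tax records
  radiocarbon_engine.py     curves, (un)calibration, SPDs, taphonomy
  growth_rates.py           point formula, exponential fits, segment rates
  wavelet_coherence.py      Morlet CWT, coherence, Monte-Carlo significance
  pipeline.py               experiment orchestration, reports, provenance
  cli.py                    click command-line interface
scripts/acceptance.py       acceptance-target report
scripts/tune_dynamics.py    scan behind the default dynamics parameters
data/growth_rate_compilation.csv   static literature reference values
```
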