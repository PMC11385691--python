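# sbtkin

Pharmacokinetic modelling and diagnostic evaluation of **¹³C-sucrose breath
test (¹³C-SBT)** curves.

The ¹³C-SBT probes intestinal sucrase-isomaltase (SIM) activity: ingested
¹³C-labelled sucrose is hydrolysed, absorbed and oxidised, and the label
appears on breath as ¹³CO₂. Reduced SIM activity — as in environmental
enteric dysfunction — slows label recovery. `sbtkin` turns a set of breath
curves into a diagnostic readout: it fits a mechanistic transit model to
each percent-dose-recovery-rate (PDRr) curve, derives empirical and
model-based classifiers of SIM inhibition, and evaluates single and
consensus classifiers across test durations with ROC/AUC, Youden-optimal
thresholds, and Matthews correlation (MCC).

## The model

The PDRr curve is modelled as the density of a two-stage transit time —
a gamma-distributed stage (shape 2, rate ρ) convolved with an exponential
stage (rate πρ) — scaled by 100κ, where κ ∈ (0, 1] is the fraction of
label ever exhaled. For π ≠ 1,

    y(t) = 100κπρ/(1−π)² · (e^(−πρt) + ((π−1)ρt − 1)e^(−ρt)),

and the cumulative recovery Y(t) = ∫₀ᵗ y is available in closed form, with
Y(∞) = 100κ. At π = 1 the transit time is Gamma(3, ρ); the implementation
switches to a series form near that point to avoid cancellation.

Parameters θ = (ρ, πρ, κ) are estimated per curve by minimizing a Gaussian
negative log-likelihood with fixed residual SD σ = 0.555 (PDRr units),
multi-started over a Latin hypercube. When the PDRr peak is not observed
within the test window (slow curves, short tests), κ is unidentifiable and
a penalty 0.1κ is added to the objective.

Four classifiers are derived from each fit:

| classifier | definition | inhibition signal |
|---|---|---|
| ρ | model rate, h⁻¹ | low |
| cPDR90 | Y(90 min), % of dose | low |
| T₅₀(ω) | time to half of Y(ω) | high |
| T_peak | argmax y(t) | high |

## Worked example

```python
import sbtkin as s

# a synthetic crossover cohort: 16 participants x {0, 100, 750 mg inhibitor}
report = s.run_analysis(s.AnalysisConfig(
    cohort=s.CohortConfig(seed=1), fit=s.FitConfig(seed=1), seed=1))

print(report.auc_grid.query(
    "classifier == 'cpdr90' and grouping == 'severe_vs_none_mild'"))
print(report.projection.groupby("duration_min")["projection_nll"].median())
```

prints

```
   classifier             grouping  duration_min       auc
5      cpdr90  severe_vs_none_mild            60  0.984375
21     cpdr90  severe_vs_none_mild            90  0.958984
37     cpdr90  severe_vs_none_mild           120  0.957031
53     cpdr90  severe_vs_none_mild           240  0.958984
duration_min
60     162.675185
90      59.756180
120     23.646613
240     12.291184
Name: projection_nll, dtype: float64
```

i.e. cPDR90 separates severe inhibition from none-to-mild with AUC ≈ 0.96
at every test duration — even a 60-minute test — while the *model fits
themselves* degrade sharply below 120 minutes (median projection NLL of
60-min fits is ~13× that of full-duration fits: a short test can classify
well even when it cannot predict the later curve).

`s.write_report(report, "out/")` writes tidy CSVs (`fits.csv`,
`classifiers.csv`, `projection_nll.csv`, `auc_grid.csv`,
`metrics_<duration>.csv`, `roc_points/…`) plus a `manifest.json`.

A CLI wraps the same pipeline:

```
sbtkin simulate --seed 1 --outdir sim/
sbtkin run-all --synthetic --seed 1 --outdir out/
sbtkin run-all --input my_curves.csv --outdir out/   # long-format CSV
```

Input CSV schema: `participant_id, condition, time_min, pdr_pct_per_h,
exclude` (exclude optional 0/1, e.g. colonic-fermentation spikes).

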