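# glowcurve-qc

Quality control for thermoluminescent-dosimeter (TLD) glow curves.

External dosimetry laboratories estimate occupational radiation doses by
heating LiF:Mg,Ti crystals and digitizing the emitted light current into a
200-channel *glow curve* whose integral is proportional to the absorbed
dose. Before the dose algorithm runs, every curve must be screened for
shape anomalies — contamination pedestals, widened or shifted peaks,
electronic spikes — that would corrupt the dose estimate. Historically a
technician reviews these curves by hand; this package automates the triage
so only genuinely problematic dosimeters reach a human.

## What it does

For each dosimeter record (3–4 element curves + reader doses L1..L4 in
mrem + read dates) the pipeline runs, in order:

1. **Background reduction** — `Bgd = RadiationPerWeek · (day2 − day1)/7`
   mrem accrued over the wear period, floored at 1 mrem, subtracted from
   every element dose.
2. **Low-dose filter** — dosimeters whose post-background total is ≤ 16
   mrem stay below the 20 mrem reporting level and are set aside.
3. **ANN pre-filter** — a fixed 202→5→15→5→1 network scores P(normal) from
   the max-normalized channels plus the skewness and kurtosis of the curve
   treated as a distribution over channel index. Curves scoring strictly
   above 0.91 are passed as normal; the threshold is deliberately high so
   the filter errs toward sending normal curves onward rather than waving
   anomalous ones through.
4. **Element-ratio plausibility** — doses must either be mutually
   consistent, `(max − min)/max < Crystals_Quotient`, or match a tabulated
   radiation field via the four inter-element dose ratios (L4/L3, L3/L1,
   L3/L2, L1/L4); otherwise the dosimeter goes to manual review.
5. **Rule cascade** — spikes (class **D**: more than `NSpikes` firings of a
   relative neighbor-difference rule) preempt everything; surviving curves
   are despiked by linear interpolation, then tested for elevated
   low/high-temperature background (**A_LOW**/**A_HIGH**, which may
   co-occur), shifted peak (**C**, argmax outside channel 95 ±
   `MaxAllowedShift`), abnormal width (**B** wide/narrow), and finally the
   catch-all class **E**.
6. **Correction** — class-A curves are corrected by zeroing the
   contaminated end (channels ≤ `LowCutCh` or ≥ `HighCutCh`) and
   recomputing the dose from the remaining integral; applied automatically
   under `bFullAutomated`, otherwise suggested for technician approval.
7. **Reporting** — every dosimeter leaves one append-only row (curve
   statistics, filter provenance, labels, corrections) in an embedded
   SQLite store, queryable by date range, reader and class.

Because reader databases are private, the package ships a synthetic
glow-curve simulator (`glowcurve_qc.simulate`) that generates normal
morphology (dominant peak at channel 95 ≈ 205 °C, two satellite peaks) and
injects every anomaly class with magnitudes that the rule cascade provably
recovers — it is both the training-data source and the test fixture
factory.

## Worked example

```bash
glowcurve-qc simulate --n 50 --seed 7 --out batch.csv
glowcurve-qc train --seed 1 --out model.json
glowcurve-qc classify --in batch.csv --model model.json \
    --out outcomes.csv --stats-db stats.sqlite --auto
glowcurve-qc report --stats-db stats.sqlite
```

The `train` step prints the held-out metrics of the filter trained on the
default 1,608-curve synthetic corpus (144 anomalous), split 60/20/20:

```json
{"split_sizes": [964, 322, 322], "n_test": 322,
 "test_log_loss": 0.0189, "anomalous_recall": 0.9655,
 "normal_pass_rate": 0.9932}
```

i.e. 96.6% of held-out anomalous curves are kept for the cascade and 99.3%
of normal curves are filtered away. `classify` then logs the stage funnel
and prints the class distribution:

```
{"stage": "input", "n_in": 50, "n_out": 50, "quarantined": 0}
{"stage": "low_dose_filter", "n_in": 50, "n_out": 35}
{"stage": "ai_filter", "n_in": 35, "n_out": 3}
{"stage": "ratio_filter", "n_in": 3, "n_out": 3}
below_reporting    15
ai_normal          32
A_LOW               1
A_HIGH              1
B_WIDE              1
```

Of 50 simulated dosimeters, 15 stayed under the reporting level, 32 were
passed as normal by the ANN, and the three injected anomalies were
classified (the two class-A curves were also auto-corrected under
`--auto`).

The same functionality is available as a library; the two classifier
components are scikit-learn-style estimators (`NormalCurveFilter`,
`RuleCascadeClassifier`) that compose with sklearn tooling:

```python
from glowcurve_qc import PipelineConfig, RuleCascadeClassifier, simulate_records
from glowcurve_qc.reporting import run_pipeline

records, labels = simulate_records(100, seed=0)
result = run_pipeline(records, config=PipelineConfig())
print(result.summary)
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantities from
scratch — the background credited for a 7-day wear period and the floor
value returned for a negative elapsed interval, both via the actual
background-reduction code path:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/glowcurve_qc/datamodel.py` — curve/record containers, configuration schema, ratio table, I/O dialects
- `src/glowcurve_qc/simulate.py` — synthetic curves, anomaly injection, labeled corpora
- `src/glowcurve_qc/prefilters.py` — background, low-dose and ratio filters
- `src/glowcurve_qc/ai_filter.py` — feature extraction, ANN filter, training protocol, model persistence
- `src/glowcurve_qc/cascade.py` — spike rule, smoothening, A/B/C/D/E cascade
- `src/glowcurve_qc/correction.py` — class-A correction and dose recomputation
- `src/glowcurve_qc/reporting.py` — SQLite statistics store, distribution summaries, pipeline driver
- `docs/methods.md` — model assumptions, parameter defaults and numerical choices
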