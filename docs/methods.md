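# Methods

This note documents the models, parameter choices and numerical decisions
behind `glowcurve-qc`: what each stage assumes, which defaults were open
design choices, and what a passing test does and does not establish.

## Signal model and conventions

A glow curve is 200 non-negative intensities in arbitrary
photomultiplier-current units, indexed by 1-based channel. The dosimetric
glow peak of LiF:Mg,Ti under a 25 °C/s heating profile sits near 205 °C,
which this package pins to channel 95; all shift- and background-related
rules are anchored there. A linear channel→temperature map (T = 15 + 2·ch,
so T(95) = 205 °C) is provided for display only — no classifier consumes
temperature.

Doses are millirem throughout (1 mrem = 0.01 mSv); the 0.2 mSv reporting
level is stored as 20 mrem, and the low-dose cut is 16 mrem so that a
filtered dosimeter stays under the reporting level once its subtracted
background (≥ 1 mrem, typically ~4 mrem for a monthly wear period) is
credited back.

## Stage-by-stage assumptions

**Background.** Ambient background accrues linearly at `RadiationPerWeek`
(default 1 mrem/week) over the wear interval. Fractional weeks are kept as
real numbers; any computed value below 1 mrem — including inverted or
missing date pairs — is floored to 1 mrem. The floor makes the stage total
and removes the need to special-case degenerate date metadata.

**Low-dose filter.** Element doses below their per-element thresholds
(`Threshold1..3`, `ThresholdNeut`, strict `<`) are zeroed before the total
is compared against the 16 mrem cut (inclusive `≤`). Whether sub-threshold
elements should be zeroed or should discard the dosimeter was an open
choice; zeroing is the conservative reading and the zeroed elements are
flagged in the decision output. Element thresholds default to 1 mrem,
i.e. they only remove essentially-unexposed elements.

**ANN filter.** The architecture is fixed (202→5→15→5→1). Open choices and
their resolutions: ReLU hidden activations, logistic output, cross-entropy
loss, adam (lr 1e-3, batch 64), because that is the smallest standard
configuration satisfying the input/output contract; channel values are
normalized by the curve maximum so the network judges shape only (dose
magnitude is the earlier filters' job); skewness and excess kurtosis are
the standardized 3rd/4th moments of the curve treated as a probability
mass function over channel index (neutral zeros for a single-channel
curve). Training uses a deterministic stratified 60/20/20
train/validation/test split (train size rounded down: 964/322/322 on the
1,608-curve default corpus), early stopping on validation cross-entropy
(patience 25, max 400 epochs) with the best-validation weights retained.
The decision comparison is strict (`P(normal) > 0.91` passes); boundary
curves go to the cascade, consistent with preferring false negatives.
Models persist as self-describing JSON (layer sizes + weights + training
metadata); inference is a plain numpy forward pass, so a saved model has no
dependency on the training stack, and retraining with the same seed
reproduces the file byte-for-byte.

**Ratio filter.** The spread test `(max − min)/max < Crystals_Quotient` is
scale- and permutation-invariant; a zero maximum cannot be judged and
routes to manual review. Table matching uses absolute tolerance (±tol on
each ratio value) since the parameter is documented on a 0–1 scale. For
3-element records the two L4 ratios are skipped and rows match on the
computable ratios alone. A measured ratio with a zero denominator and
positive numerator (+inf) matches a row only where the tabulated value's
reciprocal is within tol of zero; 0/0 is treated like an absent element.
Among multiple matching rows the one with the smallest maximum deviation
is returned — with loose tolerances several rows can match (equal doses
match NS60, H150 *and* Cs-137 at tol 0.05), and the nearest row is the
physically meaningful report.

**Spike rule (class D).** For each i in 1..197 with f = 1 +
`SpikeNeighDiff`/100: fire iff `Ch[i+1] > Ch[i]·f` and (`Ch[i+1] >
Ch[i+2]·f` or `Ch[i+2] > Ch[i+3]·f`) — a sharp rise followed by a sharp
fall one or two channels later. Adjacent firings are merged into one spike
event so a single physical spike counts once. Class D requires strictly
more than `NSpikes` events and preempts all other classes. Smoothening
replaces the elevated channels (`Ch[i+1]`, plus `Ch[i+2]` when only the
two-channel condition explains the fall) by linear interpolation between
the nearest non-spike neighbors, leaving every other channel bit-identical;
it is idempotent once all spikes are removed in one pass.

**Cascade.** Evaluation order is D (raw curve) → smoothen → A → C → B → E
on the smoothed curve. Argmax ties break to the lowest channel; all channel
windows are inclusive on both ends. The class-A and class-B peak-position
precondition (argmax within 95 ± `MaxAllowedShift`) failing routes to class
C, which is exactly the shifted-peak case. Class-A bands are strict
inequalities on the window mean relative to the curve maximum. In the
narrow test, an empty flank window (peak closer than `half_width_num_ch`
to an edge) is vacuously below threshold.

**Correction.** Only class A is correctable: channels 1..`LowCutCh`
(A_LOW) and/or `HighCutCh`..200 (A_HIGH) are replaced by zero rather than
an extrapolated baseline — the removed quantity is then exactly auditable
as the dose delta, and real normal curves carry ≲0.5% of their integral in
those ranges. Corrections never increase the dose. Automatic application
requires both `bFullAutomated` and a total dose at or below
`ManualReviewThreshold`; above it a correction is only ever suggested.
The corrected dose is reported alongside the original; it does not feed
back into the reporting-level decision.

## Parameter defaults

Printed names, defaults and units (channel windows are 1-based inclusive):

| Parameter | Default | Why |
|---|---|---|
| RadiationPerWeek | 1 mrem/week | stated weekly ambient accrual |
| low_dose_cut / reporting_level | 16 / 20 mrem | reporting-level arithmetic above |
| Crystals_Quotient | 0.25 | tolerates ±4% element sensitivity plus noise; rejects 2× spreads |
| ratio_table_threshold | 0.05 | separates adjacent table rows while accepting measurement scatter |
| ai_probability_threshold | 0.91 | high threshold encoding the false-negative preference |
| MinBgdHeight / MaxBgdHeight | 15 / 50 % | pedestals land mid-band; widened (class-B) curves' tails stay below 15% |
| BgdLTTLCh / BgdHTTLCh windows | 1–40 / 160–200 | outside ±3σ of every normal peak |
| LowCutCh / HighCutCh | 40 / 160 | coincide with the background windows |
| TLDWideLowCh–TLDWideHighCh, WideAvgVal | 50–140, 60% | normal curves average 30–42% of max here, blurred ones > 70% |
| half_width_num_ch, NarrowAvgVal | 25, 2% | normal flank means are 2.9–9.3% of max, compressed curves ~0 |
| MaxAllowedShift | 10 channels | ±20 °C; normal peak jitter is ±2 channels |
| NSpikes, SpikeNeighDiff | 3, 50% | noise at 5% CV never fires the 50% rule; a handful of spikes is tolerated and smoothed |
| ManualReviewThreshold | 500 mrem | high-dose dosimeters always get human eyes |
| dose_calibration | 0.003 mrem/unit | places a typical simulated curve (integral ≈ 3·10⁴) near 100 mrem |

The height thresholds were calibrated **once** against the simulator's
stated morphology (measured normal ranges quoted above) so that default
anomaly magnitudes are unambiguous, and are not tuned per dataset.

## The simulator: what it emulates and what it does not

Normal curves are sums of asymmetric Gaussians — main peak at channel
93–97 (σ 7–9.5, high-temperature tail 1.05–1.25× wider), two satellites
near channels 60 and 120 at ≤ 30% of the main height — with per-channel
multiplicative Gaussian noise (default CV 5%) on top of a 0.5% dark-current
baseline. The baseline matters: without it, tail channels fluctuate between
near-zeros and the *relative* spike rule fires on noise. First-order
kinetics (Randall–Wilkins) shapes, dose response, fading, and reader-to-
reader response drift are deliberately not modeled; every classifier here
consumes channel statistics, so Gaussian morphology is sufficient, and a
kinetics-based generator could replace this one without interface changes.

Anomaly injection defaults: A adds a 30%-of-max pedestal over the matching
background window; B_WIDE convolves with a σ=25-channel Gaussian kernel
(keeping peak centers fixed — an axis stretch would relocate the satellite
peaks into the class-A windows and confound the classes); B_NARROW
compresses the channel axis 4× about the peak; C shifts the whole curve by
±20 channels (zero-filling the vacated range); D multiplies 5 isolated
channels by 3×, restricted to channels carrying ≥10% of the maximum so
spikes are visible at plot scale as physical flashes are; E adds a broad
random bump and resamples until the cascade assigns E (generate-and-
filter, documented as such). Records built by `simulate_records` share one
morphology across their four elements with ±4% sensitivity scatter and use
one injection seed per record, so element-dose ratios survive the anomaly
— as they do when a physical cause affects the whole card.

Consequently, a green simulator-faithfulness test establishes that the
cascade implements its rules consistently with the stated anomaly
morphology at the stated magnitudes — not that these thresholds are
optimal for any particular laboratory's reader fleet, whose anomaly
magnitudes are unknown here. Likewise the ANN's near-perfect held-out
metrics reflect the clean separation of the synthetic classes, not
expected field performance.

## Numerical choices and degenerate inputs

- Strict vs inclusive comparisons follow the rule statements: spike counts
  and the AI threshold are strict; the low-dose cut is inclusive at 16.
- Argmax ties break to the lowest channel.
- CSV round trips are bit-exact (floats written with `repr`, parsed with
  pandas' round-trip parser).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); training determinism extends to
  byte-identical persisted models.
- All-zero curves are rejected by feature extraction (a shapeless curve is
  the low-dose filter's case); in the pipeline driver any per-record
  failure quarantines that record and the run continues.

## Known limitations

- The rule thresholds are calibrated to the simulator's stated world; a
  deployment against real reader data would re-derive the height windows
  from technician-labeled curves.
- Class E is defined negatively (none of A–D), so its simulator arm is
  generate-and-filter rather than an independent morphology.
- The ANN trains on synthetic data only; no pretrained laboratory weights
  are shipped.
- The statistics store is a single-file SQLite database; it is append-only
  by convention, not enforced by schema constraints.
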