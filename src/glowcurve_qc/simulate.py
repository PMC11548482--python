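"""Synthetic glow-curve generator with labeled anomaly injection.

The laboratory reader database behind the original study is private, so
this module is the package's data source for training and testing: it
produces normal curves with the canonical morphology (dominant dosimetric
peak at channel 95, two smaller satellite peaks, multiplicative noise) and
injects each anomaly class with magnitudes that are unambiguous under the
default configuration.

Peaks are asymmetric Gaussians (independent left/right widths) rather than
first-order-kinetics forms: every classifier in the package consumes channel
statistics only, so morphological realism at the Gaussian level suffices.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import cascade as _cascade
from .datamodel import (
    EXPECTED_PEAK_CHANNEL,
    N_CHANNELS,
    DosimeterRecord,
    GlowCurve,
    Label,
    PipelineConfig,
)

NORMAL = "NORMAL"

_X = np.arange(1, N_CHANNELS + 1, dtype=float)


@dataclass(frozen=True)
class PeakSpec:
    """One glow peak: asymmetric Gaussian.

    ``width`` is the left-side standard deviation in channels; the right
    side uses ``width * asymmetry`` (real peaks tail toward high
    temperature, so asymmetry >= 1 is typical).
    """

    center: float
    width: float
    height: float
    asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.center <= N_CHANNELS:
            raise ValueError(f"peak center {self.center} outside 1..{N_CHANNELS}")
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.height < 0:
            raise ValueError("peak height must be non-negative")
        if self.asymmetry <= 0:
            raise ValueError("peak asymmetry must be positive")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        sigma = np.where(x < self.center, self.width, self.width * self.asymmetry)
        return self.height * np.exp(-0.5 * ((x - self.center) / sigma) ** 2)


#: Default normal morphology: dosimetric main peak at channel 95 plus two
#: satellite peaks at <= 30% of the main height.
DEFAULT_PEAKS = (
    PeakSpec(center=95.0, width=8.0, height=1000.0, asymmetry=1.15),
    PeakSpec(center=60.0, width=10.0, height=200.0),
    PeakSpec(center=120.0, width=12.0, height=300.0),
)


@dataclass(frozen=True)
class AnomalySpec:
    """Which anomaly to inject and how strongly.

    Only the parameters relevant to ``label`` are used: pedestal_* for A,
    blur_sigma for B_WIDE, compress for B_NARROW, shift for C (sign comes
    from the sub-class), n_spikes/spike_amplitude for D, max_attempts for
    the generate-and-filter class E loop.
    """

    label: Label
    pedestal_frac: float = 0.3
    pedestal_window: Optional[tuple] = None  # defaults per sub-class
    blur_sigma: float = 25.0
    compress: float = 4.0
    shift: int = 20
    n_spikes: int = 5
    spike_amplitude: float = 3.0
    spike_region: tuple = (30, 170)
    max_attempts: int = 50

    def __post_init__(self) -> None:
        for name in ("pedestal_frac", "blur_sigma", "compress", "shift", "n_spikes", "spike_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_normal_gc(
    seed: int,
    peaks: Optional[Sequence[PeakSpec]] = None,
    noise_cv: float = 0.05,
) -> GlowCurve:
    """A normal glow curve: superposed peaks plus multiplicative noise.

    ``noise_cv`` is the coefficient of variation of the per-channel
    multiplicative Gaussian noise, applied on top of a small constant
    dark-current baseline (0.5% of the maximum) so that tail channels keep
    realistic relative fluctuations instead of ratios between near-zeros.
    With ``noise_cv = 0`` the curve is the exact noiseless superposition.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    peaks = tuple(peaks) if peaks is not None else DEFAULT_PEAKS
    for p in peaks:
        if not isinstance(p, PeakSpec):
            raise TypeError("peaks must be PeakSpec instances")
    y = np.zeros(N_CHANNELS)
    for p in peaks:
        y += p.evaluate(_X)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        y = (y + 0.005 * y.max()) * (1.0 + noise_cv * rng.standard_normal(N_CHANNELS))
    return GlowCurve(np.clip(y, 0.0, None))


def _inject_pedestal(y: np.ndarray, window: tuple, frac: float) -> np.ndarray:
    lo, hi = window
    out = y.copy()
    out[lo - 1 : hi] += frac * y.max()
    return out


def _inject_shift(y: np.ndarray, shift: int) -> np.ndarray:
    peak = int(np.argmax(y)) + 1
    if not 1 <= peak + shift <= N_CHANNELS:
        raise ValueError(f"shift {shift:+d} pushes the peak (channel {peak}) outside 1..{N_CHANNELS}")
    return np.interp(_X - shift, _X, y, left=0.0, right=0.0)


def _inject_spikes(y: np.ndarray, spec: AnomalySpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.spike_region
    out = y.copy()
    chosen: list[int] = []
    # spikes ride on real signal (flashes are visible at plot scale), so the
    # multiplied value is a sizeable fraction of the curve maximum
    candidates = [c for c in range(lo, hi + 1) if y[c - 1] >= 0.1 * y.max()]
    rng.shuffle(candidates)
    for c in candidates:
        if len(chosen) == spec.n_spikes:
            break
        if all(abs(c - p) >= 5 for p in chosen):  # keep spike events separable
            chosen.append(c)
    if len(chosen) < spec.n_spikes:
        raise ValueError("could not place the requested number of spikes")
    for c in chosen:
        out[c - 1] *= spec.spike_amplitude
    return out


def _inject_e_distortion(gc: GlowCurve, spec: AnomalySpec, rng: np.random.Generator) -> np.ndarray:
    """Generate-and-filter: add a broad smooth bump until the cascade says E."""
    cfg = PipelineConfig()
    for _ in range(spec.max_attempts):
        center = rng.uniform(55, 135)
        height = rng.uniform(0.4, 0.9) * gc.max
        sigma = rng.uniform(12, 28)
        bump = height * np.exp(-0.5 * ((_X - center) / sigma) ** 2)
        y = gc.channels + bump
        if _cascade.classify(GlowCurve(y), cfg).labels == frozenset({Label.E}):
            return y
    raise RuntimeError("failed to synthesize a class-E distortion; widen max_attempts")


def inject_anomaly(gc: GlowCurve, spec: AnomalySpec, seed: int = 0) -> GlowCurve:
    """Inject one anomaly into a curve; the returned curve, classified with
    the default configuration, receives the injected label (the
    simulator-classifier consistency contract, exact at zero noise)."""
    rng = np.random.default_rng(seed)
    y = gc.channels
    label = spec.label
    if label in (Label.A_LOW, Label.A_HIGH):
        window = spec.pedestal_window or ((1, 40) if label is Label.A_LOW else (160, 200))
        out = _inject_pedestal(y, window, spec.pedestal_frac)
    elif label is Label.B_WIDE:
        # blur keeps peak centers fixed, unlike an axis stretch
        out = gaussian_filter1d(y, spec.blur_sigma, mode="constant", cval=0.0)
    elif label is Label.B_NARROW:
        peak = int(np.argmax(y)) + 1
        out = np.interp(peak + (_X - peak) * spec.compress, _X, y, left=0.0, right=0.0)
    elif label is Label.C_HIGH:
        out = _inject_shift(y, abs(spec.shift))
    elif label is Label.C_LOW:
        out = _inject_shift(y, -abs(spec.shift))
    elif label is Label.D:
        out = _inject_spikes(y, spec, rng)
    elif label is Label.E:
        out = _inject_e_distortion(gc, spec, rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown anomaly label {label}")
    return GlowCurve(np.clip(out, 0.0, None))


ANOMALY_LABELS = tuple(Label)

#: Anomalous share of the default training corpus (144 of 1608 curves).
DEFAULT_ANOMALOUS_FRACTION = 144 / 1608


def _varied_peaks(rng: np.random.Generator) -> tuple:
    """Peak preset with realistic record-to-record variation."""
    height = float(rng.uniform(200, 2000))
    main = PeakSpec(
        center=float(rng.uniform(93, 97)),
        width=float(rng.uniform(7, 9.5)),
        height=height,
        asymmetry=float(rng.uniform(1.05, 1.25)),
    )
    sat1 = PeakSpec(
        center=float(rng.uniform(57, 63)),
        width=float(rng.uniform(9, 11.5)),
        height=height * float(rng.uniform(0.12, 0.28)),
    )
    sat2 = PeakSpec(
        center=float(rng.uniform(117, 123)),
        width=float(rng.uniform(10.5, 13.5)),
        height=height * float(rng.uniform(0.2, 0.3)),
    )
    return (main, sat1, sat2)


def _varied_normal(rng: np.random.Generator, noise_cv: float) -> GlowCurve:
    """A normal curve with realistic record-to-record variation."""
    return generate_normal_gc(int(rng.integers(2**31)), peaks=_varied_peaks(rng), noise_cv=noise_cv)


def _class_counts(n_anom: int, class_mix: Optional[dict]) -> dict:
    """Deterministic per-class allocation of ``n_anom`` curves."""
    if class_mix is None:
        class_mix = {l: 1.0 for l in ANOMALY_LABELS}
    labels = [Label(l) for l in class_mix]
    weights = np.asarray([class_mix[l] for l in class_mix], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("class_mix weights must be non-negative with a positive sum")
    exact = weights / weights.sum() * n_anom
    counts = np.floor(exact).astype(int)
    # hand out the remainder by largest fractional part (ties: label order)
    order = np.argsort(-(exact - counts), kind="stable")
    for k in order[: n_anom - counts.sum()]:
        counts[k] += 1
    return {labels[i]: int(counts[i]) for i in range(len(labels))}


def generate_labeled_dataset(
    n_total: int,
    anomalous_fraction: float = DEFAULT_ANOMALOUS_FRACTION,
    class_mix: Optional[dict] = None,
    seed: int = 0,
    noise_cv: float = 0.05,
) -> list:
    """Labeled corpus of (GlowCurve, label) pairs.

    The default fraction mirrors the reference training corpus imbalance
    (144 anomalous of 1608).  Class counts are exact and reproducible from
    the seed; labels are the anomaly-class names or ``"NORMAL"``.
    """
    if not 0 <= anomalous_fraction <= 1:
        raise ValueError("anomalous_fraction must lie in 0..1")
    if n_total == 0:
        return []
    rng = np.random.default_rng(seed)
    n_anom = round(n_total * anomalous_fraction)
    counts = _class_counts(n_anom, class_mix)
    data = []
    for _ in range(n_total - n_anom):
        data.append((_varied_normal(rng, noise_cv), NORMAL))
    for label, k in counts.items():
        for _ in range(k):
            base = _varied_normal(rng, noise_cv)
            gc = inject_anomaly(base, AnomalySpec(label=label), seed=int(rng.integers(2**31)))
            data.append((gc, label.value))
    perm = rng.permutation(len(data))
    return [data[i] for i in perm]


def simulate_records(
    n: int,
    seed: int = 0,
    anomalous_fraction: float = DEFAULT_ANOMALOUS_FRACTION,
    below_reporting_fraction: float = 0.3,
    class_mix: Optional[dict] = None,
    noise_cv: float = 0.05,
    config: Optional[PipelineConfig] = None,
) -> tuple:
    """Full dosimeter records for pipeline-level runs.

    Each record carries 4 element curves sharing one morphology (anomalies
    are injected into every element, as a physical cause would); element
    doses are the calibrated curve integrals, so equal-field records pass
    the ratio filter.  ``below_reporting_fraction`` of records are scaled so
    their post-background total stays under the reporting level.

    Returns ``(records, labels)`` where the label is ``"NORMAL"``,
    ``"BELOW"`` or the injected anomaly class.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    n_below = round(n * below_reporting_fraction)
    n_anom = round((n - n_below) * anomalous_fraction)
    counts = _class_counts(n_anom, class_mix)
    plan = ["BELOW"] * n_below + [l.value for l, k in counts.items() for _ in range(k)]
    plan += [NORMAL] * (n - len(plan))
    rng.shuffle(plan)

    records, labels = [], []
    wear_days = 30
    read_date = _dt.date(2024, 3, 1)
    prev_date = read_date - _dt.timedelta(days=wear_days)
    bgd = cfg.RadiationPerWeek * wear_days / 7.0
    for k, label in enumerate(plan):
        if label == "BELOW":
            # post-background total comfortably under the low-dose cut
            target_total = float(rng.uniform(2, cfg.low_dose_cut * 0.8))
        else:
            target_total = float(rng.uniform(80, 600))
        # the four elements of one card share the field and morphology; only
        # noise and a small per-element sensitivity factor differ
        peaks = _varied_peaks(rng)
        base_seed = int(rng.integers(2**30))
        curves = []
        for e in range(4):
            gc = generate_normal_gc(base_seed + e, peaks=peaks, noise_cv=noise_cv)
            sens = float(rng.uniform(0.96, 1.04))
            gc = GlowCurve(gc.channels * sens)
            if label not in (NORMAL, "BELOW"):
                # one seed per record: the same physical cause hits every element,
                # so injected magnitudes stay proportional and dose ratios survive
                gc = inject_anomaly(gc, AnomalySpec(label=Label(label)), seed=base_seed + 100)
            curves.append(gc)
        # scale all elements to the target total dose (keeps ratios ~ equal)
        integ = sum(c.integral for c in curves)
        scale = (target_total + 4 * bgd) / (cfg.dose_calibration * integ)
        curves = [GlowCurve(c.channels * scale) for c in curves]
        doses = [cfg.dose_calibration * c.integral for c in curves]
        records.append(
            DosimeterRecord(
                dosimeter_id=f"SIM{k:05d}",
                reader_id=f"R{1 + k % 3}",
                curves=tuple(curves),
                element_doses=tuple(doses),
                read_date=read_date,
                previous_read_date=prev_date,
            )
        )
        labels.append(label)
    return records, labels
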