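"""Rule-based anomaly classification cascade.

Order of evaluation (fixed): spikes (class D) on the raw curve, then spike
smoothening, then elevated background (class A), shifted peak (class C),
abnormal width (class B), and finally the catch-all class E.  D preempts
everything; A_LOW and A_HIGH may co-occur; B, C, D and E are mutually
exclusive and exclude A.

All thresholds come from :class:`~glowcurve_qc.datamodel.PipelineConfig`;
height thresholds are percentages of the curve maximum, windows are 1-based
inclusive channel ranges, and the peak is expected at channel 95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .datamodel import (
    EXPECTED_PEAK_CHANNEL,
    N_CHANNELS,
    GlowCurve,
    Label,
    PipelineConfig,
    validate_config,
)


@dataclass(frozen=True)
class SpikeReport:
    """Spikes found by the neighbor-difference rule.

    ``positions`` are merged spike events (first firing index of each run of
    adjacent firings); ``raw_positions`` every index i (1-based, 1..197)
    where the rule fired; ``channels`` the elevated channels to be replaced
    by smoothening.
    """

    positions: tuple
    raw_positions: tuple
    channels: tuple

    @property
    def count(self) -> int:
        return len(self.positions)


def detect_spikes(gc: GlowCurve, spike_neigh_diff: float) -> SpikeReport:
    """Scan for 1-2 channel wide spikes.

    For each i in 1..197 with f = (100 + spike_neigh_diff)/100, the rule
    fires iff

        Ch[i+1] > Ch[i]*f  and  (Ch[i+1] > Ch[i+2]*f  or  Ch[i+2] > Ch[i+3]*f)

    i.e. a sharp rise followed by a sharp fall one or two channels later.
    Adjacent firings are merged into a single spike event.  The elevated
    channel is Ch[i+1], plus Ch[i+2] when only the two-channel condition
    explains the fall.
    """
    c = gc.channels
    f = (100.0 + spike_neigh_diff) / 100.0
    i0 = np.arange(N_CHANNELS - 3)  # 0-based i-1 for i = 1..197
    cond1 = c[i0 + 1] > c[i0] * f
    cond2 = c[i0 + 1] > c[i0 + 2] * f
    cond3 = c[i0 + 2] > c[i0 + 3] * f
    fired = cond1 & (cond2 | cond3)
    raw = np.nonzero(fired)[0] + 1  # back to 1-based i

    positions = []
    channels: set[int] = set()
    prev = None
    for i in raw:
        if prev is None or i != prev + 1:
            positions.append(int(i))
        prev = int(i)
        channels.add(int(i) + 1)  # Ch[i+1] is the elevated channel
        if cond3[i - 1] and not cond2[i - 1]:
            channels.add(int(i) + 2)  # two-channel-wide spike
    return SpikeReport(
        positions=tuple(positions),
        raw_positions=tuple(int(i) for i in raw),
        channels=tuple(sorted(channels)),
    )


def classify_class_d(report: SpikeReport, n_spikes: int) -> bool:
    """Class D iff strictly more than ``n_spikes`` spike events were found."""
    return report.count > n_spikes


def smoothen(gc: GlowCurve, report: SpikeReport) -> GlowCurve:
    """Replace spike channels by linear interpolation between their nearest
    non-spike neighbors; every other channel is bit-identical."""
    if not report.channels:
        return gc
    y = gc.channels.copy()
    spike = np.zeros(N_CHANNELS, dtype=bool)
    spike[[ch - 1 for ch in report.channels]] = True
    idx = 0
    while idx < N_CHANNELS:
        if not spike[idx]:
            idx += 1
            continue
        run_start = idx
        while idx < N_CHANNELS and spike[idx]:
            idx += 1
        run_end = idx - 1
        left = run_start - 1
        right = run_end + 1
        if left < 0 and right >= N_CHANNELS:
            continue  # cannot happen for <=2-channel spikes but keep safe
        if left < 0:
            y[run_start : run_end + 1] = y[right]
        elif right >= N_CHANNELS:
            y[run_start : run_end + 1] = y[left]
        else:
            xs = np.arange(run_start, run_end + 1)
            y[run_start : run_end + 1] = np.interp(xs, [left, right], [y[left], y[right]])
    return GlowCurve(y)


def _peak_in_place(gc: GlowCurve, max_allowed_shift: int) -> bool:
    return abs(gc.argmax_channel - EXPECTED_PEAK_CHANNEL) <= max_allowed_shift


def classify_class_a(gc: GlowCurve, config: PipelineConfig) -> frozenset:
    """Elevated low/high temperature background.

    Requires the peak near channel 95; each sub-class holds when the mean of
    its temperature window lies strictly between MinBgdHeight% and
    MaxBgdHeight% of the curve maximum.  Both sub-classes may hold at once.
    """
    if not _peak_in_place(gc, config.MaxAllowedShift):
        return frozenset()
    mx = gc.max
    lo_band = 0.01 * config.MinBgdHeight * mx
    hi_band = 0.01 * config.MaxBgdHeight * mx
    labels = set()
    avg_high = float(np.mean(gc.window(config.BgdHTTLChLow, config.BgdHTTLChHigh)))
    if lo_band < avg_high < hi_band:
        labels.add(Label.A_HIGH)
    avg_low = float(np.mean(gc.window(config.BgdLTTLChLow, config.BgdLTTLChHigh)))
    if lo_band < avg_low < hi_band:
        labels.add(Label.A_LOW)
    return frozenset(labels)


def classify_class_c(gc: GlowCurve, max_allowed_shift: int) -> Optional[Label]:
    """Shifted peak: C_HIGH beyond 95+shift, C_LOW below 95-shift."""
    ch_max = gc.argmax_channel
    if ch_max > EXPECTED_PEAK_CHANNEL + max_allowed_shift:
        return Label.C_HIGH
    if ch_max < EXPECTED_PEAK_CHANNEL - max_allowed_shift:
        return Label.C_LOW
    return None


def classify_class_b(gc: GlowCurve, config: PipelineConfig) -> Optional[Label]:
    """Abnormal width.

    Wide: the mean over the width-measure window exceeds WideAvgVal% of the
    maximum.  Narrow: the means of both flanks (outside +/-half_width_num_ch
    around the peak) fall below NarrowAvgVal% of the maximum; a flank that
    is empty is vacuously low.
    """
    if not _peak_in_place(gc, config.MaxAllowedShift):
        return None
    mx = gc.max
    wide_avg = float(np.mean(gc.window(config.TLDWideLowCh, config.TLDWideHighCh)))
    if wide_avg > 0.01 * config.WideAvgVal * mx:
        return Label.B_WIDE
    ch_max = gc.argmax_channel
    narrow_band = 0.01 * config.NarrowAvgVal * mx
    left_hi = ch_max - config.half_width_num_ch
    right_lo = ch_max + config.half_width_num_ch
    left = gc.window(1, left_hi)
    right = gc.window(right_lo, N_CHANNELS)
    left_ok = left.size == 0 or float(np.mean(left)) < narrow_band
    right_ok = right.size == 0 or float(np.mean(right)) < narrow_band
    if left_ok and right_ok:
        return Label.B_NARROW
    return None


@dataclass
class CascadeResult:
    """Labels plus every intermediate value of the cascade, for audit."""

    labels: frozenset
    spike_report: SpikeReport
    smoothed: GlowCurve
    trace: dict = field(default_factory=dict)


def classify(gc: GlowCurve, config: Optional[PipelineConfig] = None) -> CascadeResult:
    """Run the full cascade on one (already suspected-anomalous) curve."""
    config = config or PipelineConfig()
    report = detect_spikes(gc, config.SpikeNeighDiff)
    trace: dict = {"spike_count": report.count, "argmax_channel": gc.argmax_channel}
    if classify_class_d(report, config.NSpikes):
        trace["stage"] = "D"
        return CascadeResult(frozenset({Label.D}), report, gc, trace)
    sm = smoothen(gc, report)
    trace["argmax_channel_smoothed"] = sm.argmax_channel
    a = classify_class_a(sm, config)
    if a:
        trace["stage"] = "A"
        return CascadeResult(a, report, sm, trace)
    c = classify_class_c(sm, config.MaxAllowedShift)
    if c is not None:
        trace["stage"] = "C"
        return CascadeResult(frozenset({c}), report, sm, trace)
    b = classify_class_b(sm, config)
    if b is not None:
        trace["stage"] = "B"
        return CascadeResult(frozenset({b}), report, sm, trace)
    trace["stage"] = "E"
    return CascadeResult(frozenset({Label.E}), report, sm, trace)


class RuleCascadeClassifier(BaseEstimator):
    """sklearn-style wrapper around the rule cascade.

    The cascade has no trainable state: :meth:`fit` only validates the
    configuration.  :meth:`predict` maps an (n, 200) array of curves to
    label strings (dual class-A results join with ``|``).
    """

    def __init__(self, config: Optional[PipelineConfig] = None):
        self.config = config

    def fit(self, X=None, y=None) -> "RuleCascadeClassifier":
        cfg = self.config or PipelineConfig()
        violations = validate_config(cfg)
        if violations:
            raise ValueError("invalid configuration: " + "; ".join(violations))
        self.config_ = cfg
        return self

    def _effective_config(self) -> PipelineConfig:
        return getattr(self, "config_", None) or self.config or PipelineConfig()

    def classify_curve(self, gc: GlowCurve) -> CascadeResult:
        return classify(gc, self._effective_config())

    def predict(self, X: Sequence) -> np.ndarray:
        cfg = self._effective_config()
        out = []
        for row in X:
            gc = row if isinstance(row, GlowCurve) else GlowCurve(np.asarray(row, dtype=float))
            res = classify(gc, cfg)
            out.append("|".join(sorted(l.value for l in res.labels)))
        return np.asarray(out, dtype=object)
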