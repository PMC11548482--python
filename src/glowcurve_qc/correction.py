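"""Automatic correction of class-A glow curves.

Class A is the only correctable anomaly: the excess is background confined
to one temperature end of the curve, so the cure is to zero the affected
channel range (below ``LowCutCh`` for A_LOW, above ``HighCutCh`` for
A_HIGH) and recompute the dose from the remaining integral.  Corrections
are applied outright only when the lab runs fully automated and the
dosimeter is not above the manual-review threshold; otherwise they are
queued as suggestions for the technician.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .datamodel import N_CHANNELS, GlowCurve, Label, PipelineConfig

A_LABELS = frozenset({Label.A_LOW, Label.A_HIGH})


@dataclass(frozen=True)
class CorrectionProposal:
    dosimeter_id: str
    sub_class: str  # "A_LOW" | "A_HIGH" | "both"
    cut_channels: tuple  # ((lo, hi), ...) 1-based inclusive ranges zeroed
    dose_before: float
    dose_after: float
    status: str = "suggested"  # or "applied"

    def __post_init__(self) -> None:
        if self.dose_after > self.dose_before + 1e-9:
            raise ValueError("a correction can never increase the dose")
        for lo, hi in self.cut_channels:
            if not (1 <= lo <= hi <= N_CHANNELS):
                raise ValueError(f"cut range {lo}..{hi} outside 1..{N_CHANNELS}")

    @property
    def delta(self) -> float:
        return self.dose_before - self.dose_after


def recompute_dose(gc: GlowCurve, calibration: float) -> float:
    """Dose in mrem: calibration (mrem per unit integral) times the integral."""
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    return calibration * gc.integral


def correct_class_a(
    gc: GlowCurve,
    labels,
    config: Optional[PipelineConfig] = None,
    dosimeter_id: str = "",
) -> tuple:
    """Zero the contaminated end(s) of a class-A curve.

    Returns ``(corrected_curve, proposal)``; the proposal starts as
    "suggested" (see :func:`apply_or_suggest`).  Channels outside the cut
    ranges are bit-identical to the input.
    """
    cfg = config or PipelineConfig()
    labels = frozenset(Label(l) for l in labels)
    if not labels:
        raise ValueError("correction requires at least one class-A label")
    if labels - A_LABELS:
        bad = sorted(l.value for l in labels - A_LABELS)
        raise ValueError(f"correction is only possible for class-A curves, got {bad}")
    y = gc.channels.copy()
    cuts = []
    if Label.A_LOW in labels:
        y[: cfg.LowCutCh] = 0.0
        cuts.append((1, cfg.LowCutCh))
    if Label.A_HIGH in labels:
        y[cfg.HighCutCh - 1 :] = 0.0
        cuts.append((cfg.HighCutCh, N_CHANNELS))
    corrected = GlowCurve(y)
    proposal = CorrectionProposal(
        dosimeter_id=dosimeter_id,
        sub_class="both" if len(labels) == 2 else next(iter(labels)).value,
        cut_channels=tuple(cuts),
        dose_before=recompute_dose(gc, cfg.dose_calibration),
        dose_after=recompute_dose(corrected, cfg.dose_calibration),
    )
    return corrected, proposal


def apply_or_suggest(proposal: CorrectionProposal, b_full_automated: bool) -> CorrectionProposal:
    """Promote a proposal to "applied" under full automation; idempotent."""
    if proposal.status == "applied":
        return proposal
    return replace(proposal, status="applied" if b_full_automated else "suggested")
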