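"""Early pipeline stages: background reduction, low-dose filtering, and the
element dose-ratio plausibility filter.

Everything here operates on reader dose values (mrem), not curve shapes:
these stages decide whether a dosimeter needs shape analysis at all, and
whether its element doses are consistent with a real radiation field.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .datamodel import DosimeterRecord, PipelineConfig, RatioRow, RatioTable

logger = logging.getLogger(__name__)

#: Minimum credited background (mrem); short or inverted wear periods never
#: credit less than this.
BGD_FLOOR_MREM = 1.0


@dataclass(frozen=True)
class BackgroundResult:
    """Ambient background accumulated over the wear period."""

    bgd: float  # mrem
    elapsed_days: int


@dataclass(frozen=True)
class LowDoseDecision:
    filtered_out: bool
    adjusted_doses: tuple  # after element-threshold zeroing
    zeroed_elements: tuple  # 1-based indices of zeroed elements
    total: float


@dataclass(frozen=True)
class RatioMatch:
    beam: Optional[str]
    row: Optional[RatioRow]
    max_deviation: Optional[float]

    @property
    def matched(self) -> bool:
        return self.beam is not None


def compute_background(
    day1: Optional[_dt.date], day2: Optional[_dt.date], radiation_per_week: float = 1.0
) -> BackgroundResult:
    """Background dose accrued between two reads at a constant weekly rate.

    ``bgd = radiation_per_week * (day2 - day1) / 7`` mrem, floored at 1 mrem
    (inverted date pairs and very short periods credit the floor).  Missing
    dates also fall back to the floor, with a warning.
    """
    if radiation_per_week <= 0:
        raise ValueError("radiation_per_week must be positive")
    if day1 is None or day2 is None:
        logger.warning("missing read date(s); crediting the %.0f mrem background floor", BGD_FLOOR_MREM)
        return BackgroundResult(bgd=BGD_FLOOR_MREM, elapsed_days=0)
    elapsed = (day2 - day1).days
    bgd = radiation_per_week * elapsed / 7.0
    if bgd < BGD_FLOOR_MREM:
        bgd = BGD_FLOOR_MREM
    return BackgroundResult(bgd=bgd, elapsed_days=elapsed)


def subtract_background(record: DosimeterRecord, bgd: BackgroundResult) -> DosimeterRecord:
    """Subtract the accrued background from every element dose (floored at 0).

    The original doses are retained on ``raw_element_doses`` for audit and
    so the background can be re-credited later.
    """
    raw = record.raw_element_doses or record.element_doses
    new_doses = tuple(max(d - bgd.bgd, 0.0) for d in record.element_doses)
    return replace(record, element_doses=new_doses, raw_element_doses=raw)


def low_dose_filter(record: DosimeterRecord, config: PipelineConfig) -> LowDoseDecision:
    """Drop dosimeters that stay below the reporting level.

    Elements with a (post-background) dose under their per-element threshold
    are zeroed first; the dosimeter is filtered out when the remaining total
    is at most ``low_dose_cut`` (16 mrem: together with the re-credited
    background this keeps the result under the 20 mrem reporting level).
    """
    thresholds = config.element_thresholds(record.n_elements)
    adjusted = []
    zeroed = []
    for i, (d, t) in enumerate(zip(record.element_doses, thresholds), start=1):
        if d < t:
            adjusted.append(0.0)
            zeroed.append(i)
        else:
            adjusted.append(d)
    total = float(sum(adjusted))
    return LowDoseDecision(
        filtered_out=total <= config.low_dose_cut,
        adjusted_doses=tuple(adjusted),
        zeroed_elements=tuple(zeroed),
        total=total,
    )


def crystal_spread_check(doses: Sequence[float], quotient: float) -> bool:
    """Relative spread test: pass iff (max - min) / max < quotient.

    Scale-invariant and permutation-invariant; a zero maximum cannot be
    judged and fails (routed to manual review by the caller).
    """
    doses = [float(d) for d in doses]
    if len(doses) < 3:
        raise ValueError("need at least 3 element doses")
    mx = max(doses)
    if mx <= 0:
        return False
    return (mx - min(doses)) / mx < quotient


def _computable_ratios(doses: Sequence[Optional[float]]) -> dict:
    """Measured counterparts of the tabulated ratios.

    Keys follow the table columns; a ratio is present only when both of its
    elements are present.  num/0 with num > 0 yields +inf; 0/0 is dropped
    (treated like an absent element).
    """
    vals = {f"l{i+1}": doses[i] for i in range(len(doses))}
    if len(doses) < 4:
        vals.setdefault("l4", None)
    pairs = {
        "l4_over_l3": ("l4", "l3"),
        "l3_over_l1": ("l3", "l1"),
        "l3_over_l2": ("l3", "l2"),
        "l1_over_l4": ("l1", "l4"),
    }
    out = {}
    for key, (num_k, den_k) in pairs.items():
        num, den = vals.get(num_k), vals.get(den_k)
        if num is None or den is None:
            continue
        num, den = float(num), float(den)
        if den > 0:
            out[key] = num / den
        elif num > 0:
            out[key] = math.inf
        # 0/0: undefined, skipped
    return out


def _row_deviation(ratios: dict, row: RatioRow, tol: float) -> Optional[float]:
    """Max |measured - tabulated| over computable ratios, or None on mismatch."""
    worst = 0.0
    for key, r in ratios.items():
        v = row.ratio(key)
        if math.isinf(r):
            # a vanishing denominator matches only rows whose reciprocal is ~0
            if v > 0 and 1.0 / v <= tol:
                continue
            return None
        if abs(r - v) > tol:
            return None
        worst = max(worst, abs(r - v))
    return worst


def ratio_table_match(
    doses: Sequence[Optional[float]], table: Optional[RatioTable] = None, tol: float = 0.05
) -> RatioMatch:
    """Match the measured element-dose ratios against the radiation-field table.

    A row matches when every computable ratio lies within +/- ``tol``
    (absolute) of the tabulated value; among matching rows the one with the
    smallest maximum deviation is returned.
    """
    if table is None:
        table = RatioTable.default()
    present = [d for d in doses if d is not None]
    if len(present) < 3:
        raise ValueError("need at least 3 element doses")
    ratios = _computable_ratios(doses)
    if not ratios:
        return RatioMatch(None, None, None)
    best: Optional[tuple] = None
    for row in table.rows:
        dev = _row_deviation(ratios, row, tol)
        if dev is not None and (best is None or dev < best[0]):
            best = (dev, row)
    if best is None:
        return RatioMatch(None, None, None)
    return RatioMatch(beam=best[1].beam, row=best[1], max_deviation=best[0])


def prefilter_dosimeter(
    record: DosimeterRecord, config: PipelineConfig, table: Optional[RatioTable] = None
) -> tuple:
    """Element-dose plausibility gate: proceed or route to manual review.

    A dosimeter proceeds when its element doses are either mutually
    consistent (spread check) or consistent with a known radiation field
    (ratio-table match); otherwise a technician must look at it.

    Returns ``(decision, details)`` with decision ``"proceed"`` or
    ``"manual_review"``.
    """
    doses = list(record.element_doses)
    spread_ok = crystal_spread_check(doses, config.Crystals_Quotient)
    details: dict = {"spread_pass": spread_ok, "beam": None}
    if spread_ok:
        return "proceed", details
    match = ratio_table_match(doses, table, config.ratio_table_threshold)
    details["beam"] = match.beam
    if match.matched:
        return "proceed", details
    return "manual_review", details
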