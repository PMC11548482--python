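"""Shared domain types for glow-curve quality control.

A thermoluminescent dosimeter (TLD) card carries 3-4 LiF:Mg,Ti crystals
("elements").  When a reader heats an element, the emitted light current is
digitized into a 200-channel glow curve whose integral is proportional to
the absorbed dose.  This module holds the curve and dosimeter containers,
the configuration schema that drives every threshold in the pipeline, the
radiation-field dose-ratio table used by the plausibility filter, and the
per-dosimeter classification outcome.

Units: doses are millirem (1 mrem = 0.01 mSv); curve intensities are
arbitrary photomultiplier-current units; channels are 1-based indices
1..200.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

N_CHANNELS = 200

#: The dosimetric glow peak ("peak 5", ~205 degC) sits at channel 95 under the
#: default 25 degC/s heating profile.  The shift and background rules are
#: anchored to this channel, so it is a constant rather than a free parameter.
EXPECTED_PEAK_CHANNEL = 95


class Label(str, enum.Enum):
    """Anomaly taxonomy for glow curves.

    A: elevated background at low (A_LOW) / high (A_HIGH) temperature
    channels; B: abnormal curve width (wide/narrow); C: curve shifted to
    low/high temperatures; D: too many spikes; E: anomalous but matching no
    other class.
    """

    A_LOW = "A_LOW"
    A_HIGH = "A_HIGH"
    B_WIDE = "B_WIDE"
    B_NARROW = "B_NARROW"
    C_LOW = "C_LOW"
    C_HIGH = "C_HIGH"
    D = "D"
    E = "E"


#: Exclusive labels: a curve carries at most one of these (and then no A label).
EXCLUSIVE_LABELS = frozenset(
    {Label.B_WIDE, Label.B_NARROW, Label.C_LOW, Label.C_HIGH, Label.D, Label.E}
)


class Stage(str, enum.Enum):
    """Terminal disposition of a dosimeter in the pipeline."""

    BELOW_REPORTING = "below_reporting"
    AI_NORMAL = "ai_normal"
    MANUAL_REVIEW_RATIO_FAIL = "manual_review_ratio_fail"
    CLASSIFIED = "classified"


@dataclass(frozen=True, eq=False)
class GlowCurve:
    """A 200-channel glow curve.

    ``channels`` holds non-negative, finite intensities in arbitrary units.
    Channel indices are 1-based throughout (``ch(1)`` .. ``ch(200)``).
    """

    channels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim != 1 or arr.size != N_CHANNELS:
            raise ValueError(f"glow curve must have exactly {N_CHANNELS} channels, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("glow curve intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("glow curve intensities must be non-negative")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "channels", arr)

    def ch(self, i: int) -> float:
        """Intensity at 1-based channel ``i``."""
        if not 1 <= i <= N_CHANNELS:
            raise IndexError(f"channel {i} outside 1..{N_CHANNELS}")
        return float(self.channels[i - 1])

    def window(self, lo: int, hi: int) -> np.ndarray:
        """Channels ``lo..hi`` inclusive (1-based)."""
        if lo > hi:
            return np.empty(0)
        return self.channels[max(lo, 1) - 1 : min(hi, N_CHANNELS)]

    @property
    def max(self) -> float:
        return float(self.channels.max())

    @property
    def argmax_channel(self) -> int:
        """1-based channel of the maximum; ties break to the lowest channel."""
        return int(np.argmax(self.channels)) + 1

    @property
    def integral(self) -> float:
        return float(self.channels.sum())

    def stats(self) -> dict:
        return {
            "min": float(self.channels.min()),
            "max": self.max,
            "median": float(np.median(self.channels)),
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlowCurve):
            return NotImplemented
        return bool(np.array_equal(self.channels, other.channels))

    def __repr__(self) -> str:  # keep test failures readable
        return f"GlowCurve(max={self.max:.3g}@ch{self.argmax_channel}, integral={self.integral:.4g})"


@dataclass(frozen=True)
class ChannelTemperatureMap:
    """Linear channel -> temperature convention, for display only.

    Defaults place channel 95 at 205 degC (t0 + 95*dt with t0=15, dt=2); no
    classification rule depends on temperature.
    """

    t0: float = 15.0
    dt: float = 2.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive (temperature increases with channel)")

    def temperature(self, channel: int | np.ndarray) -> float | np.ndarray:
        return self.t0 + self.dt * np.asarray(channel, dtype=float)


@dataclass(eq=True)
class DosimeterRecord:
    """One dosimeter read: 3-4 element glow curves plus reader metadata.

    ``element_doses`` are the reader's per-element doses L1..L4 in mrem (L4,
    when present, is the thermal-neutron crystal).  ``raw_element_doses``
    keeps the pre-background values for audit once background is subtracted.
    """

    dosimeter_id: str
    reader_id: str
    curves: tuple
    element_doses: tuple
    read_date: Optional[_dt.date] = None
    previous_read_date: Optional[_dt.date] = None
    ecc: tuple = ()
    raw_element_doses: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.curves = tuple(self.curves)
        self.element_doses = tuple(float(d) for d in self.element_doses)
        if not self.ecc:
            self.ecc = tuple(1.0 for _ in self.curves)
        else:
            self.ecc = tuple(float(e) for e in self.ecc)
        n = len(self.curves)
        if n not in (3, 4):
            raise ValueError(f"a dosimeter has 3 or 4 elements, got {n}")
        if len(self.element_doses) != n or len(self.ecc) != n:
            raise ValueError("curves, element_doses and ecc must have equal length")
        if any(d < 0 for d in self.element_doses):
            raise ValueError("element doses must be non-negative")

    @property
    def n_elements(self) -> int:
        return len(self.curves)

    @property
    def total_dose(self) -> float:
        return float(sum(self.element_doses))


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, keyed by its configuration-file name.

    Dose parameters are mrem, height parameters are percent of the curve
    maximum, channel parameters are 1-based inclusive indices.  See
    docs/methods.md for the rationale behind each default.
    """

    # general
    ManualReviewThreshold: float = 500.0
    bFullAutomated: bool = False
    Threshold1: float = 1.0
    Threshold2: float = 1.0
    Threshold3: float = 1.0
    ThresholdNeut: float = 1.0
    ThresholdRing: float = 1.0
    RadiationPerWeek: float = 1.0
    Crystals_Quotient: float = 0.25
    ratio_table_threshold: float = 0.05
    MDBPath: str = ""
    # machine learning
    bUseAI: bool = True
    training_model_file: str = "filter_model.json"
    ai_probability_threshold: float = 0.91
    # class A
    MaxBgdHeight: float = 50.0
    MinBgdHeight: float = 15.0
    BgdHTTLChLow: int = 160
    BgdHTTLChHigh: int = 200
    BgdLTTLChLow: int = 1
    BgdLTTLChHigh: int = 40
    LowCutCh: int = 40
    HighCutCh: int = 160
    # class B
    TLDWideLowCh: int = 50
    TLDWideHighCh: int = 140
    WideAvgVal: float = 60.0
    half_width_num_ch: int = 25
    NarrowAvgVal: float = 2.0
    MaxAllowedShift: int = 10
    # class D
    NSpikes: int = 3
    SpikeNeighDiff: float = 50.0
    # artifact-level knobs (not reader thresholds)
    reporting_level: float = 20.0
    low_dose_cut: float = 16.0
    dose_calibration: float = 0.003
    random_seed: int = 0

    @property
    def expected_peak_channel(self) -> int:
        return EXPECTED_PEAK_CHANNEL

    def element_thresholds(self, n_elements: int) -> tuple:
        thr = (self.Threshold1, self.Threshold2, self.Threshold3, self.ThresholdNeut)
        return thr[:n_elements]


def validate_config(config: PipelineConfig) -> list:
    """Check configuration invariants; returns violations (empty = valid)."""
    v: list[str] = []
    c = config
    if not (1 <= c.BgdLTTLChLow <= c.BgdLTTLChHigh < c.BgdHTTLChLow <= c.BgdHTTLChHigh <= N_CHANNELS):
        v.append(
            "BgdLTTLChLow/BgdLTTLChHigh/BgdHTTLChLow/BgdHTTLChHigh must satisfy "
            "1 <= low-window <= high-window <= 200 with the low-temperature window below the high one"
        )
    if not (0 <= c.MinBgdHeight < c.MaxBgdHeight <= 100):
        v.append("MinBgdHeight/MaxBgdHeight must satisfy 0 <= MinBgdHeight < MaxBgdHeight <= 100")
    if not (0 < c.ai_probability_threshold < 1):
        v.append("ai_probability_threshold must lie strictly between 0 and 1")
    if c.MaxAllowedShift < 0:
        v.append("MaxAllowedShift must be >= 0")
    if c.NSpikes < 0:
        v.append("NSpikes must be >= 0")
    if c.SpikeNeighDiff <= 0:
        v.append("SpikeNeighDiff must be > 0")
    if not (1 <= c.TLDWideLowCh <= c.TLDWideHighCh <= N_CHANNELS):
        v.append("TLDWideLowCh/TLDWideHighCh must satisfy 1 <= low <= high <= 200")
    if not (1 <= c.LowCutCh <= N_CHANNELS and 1 <= c.HighCutCh <= N_CHANNELS):
        v.append("LowCutCh/HighCutCh must be channel indices in 1..200")
    if c.half_width_num_ch < 1:
        v.append("half_width_num_ch must be >= 1")
    if c.RadiationPerWeek <= 0:
        v.append("RadiationPerWeek must be > 0")
    if not (0 <= c.Crystals_Quotient <= 1):
        v.append("Crystals_Quotient must lie in 0..1")
    if not (0 <= c.ratio_table_threshold <= 1):
        v.append("ratio_table_threshold must lie in 0..1")
    if c.dose_calibration <= 0:
        v.append("dose_calibration must be > 0")
    return v


def load_config(path) -> PipelineConfig:
    """Read a YAML configuration keyed by the exact parameter names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def config_from_dict(data: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown configuration parameters: {', '.join(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Radiation-field ratio table
# ---------------------------------------------------------------------------

RATIO_KEYS = ("l4_over_l3", "l3_over_l1", "l3_over_l2", "l1_over_l4")


@dataclass(frozen=True)
class RatioRow:
    l4_over_l3: float
    l3_over_l1: float
    l3_over_l2: float
    l1_over_l4: float
    energy_kev: Optional[float]
    beam: str

    def ratio(self, key: str) -> float:
        return float(getattr(self, key))


@dataclass(frozen=True)
class RatioTable:
    """Reference element-dose ratios for plausible radiation fields.

    Each row gives the four inter-element dose ratios expected for one
    calibration beam (narrow/medium/wide X-ray series, Cs-137, beta
    sources); a dosimeter whose measured ratios match some row was exposed
    to a physically plausible field.
    """

    rows: tuple

    @classmethod
    def default(cls) -> "RatioTable":
        with importlib.resources.files("glowcurve_qc.data").joinpath("ratio_table.csv").open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RatioTable":
        df = pd.read_csv(path_or_buf)
        rows = tuple(
            RatioRow(
                l4_over_l3=float(r.l4_over_l3),
                l3_over_l1=float(r.l3_over_l1),
                l3_over_l2=float(r.l3_over_l2),
                l1_over_l4=float(r.l1_over_l4),
                energy_kev=None if pd.isna(r.energy_kev) else float(r.energy_kev),
                beam=str(r.beam),
            )
            for r in df.itertuples()
        )
        return cls(rows=rows)

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Classification outcome
# ---------------------------------------------------------------------------


@dataclass
class ClassificationOutcome:
    """Per-dosimeter result: disposition, labels, and decision provenance."""

    dosimeter_id: str
    stage_reached: Stage
    labels: frozenset = frozenset()
    ai_probability: Optional[float] = None
    spike_count: int = 0
    corrected: bool = False
    correction_delta: float = 0.0
    stats: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = frozenset(Label(l) for l in self.labels)
        excl = self.labels & EXCLUSIVE_LABELS
        a = self.labels - EXCLUSIVE_LABELS
        if excl and a:
            raise ValueError("class A labels cannot coexist with B/C/D/E labels")
        if len(excl) > 1:
            raise ValueError(f"labels {sorted(l.value for l in excl)} are mutually exclusive")

    @property
    def primary_label(self) -> str:
        if not self.labels:
            return ""
        return "|".join(sorted(l.value for l in self.labels))


# ---------------------------------------------------------------------------
# Record (de)serialization: CSV and JSON-lines dialects
# ---------------------------------------------------------------------------

CHANNEL_COLUMNS = [f"ch{i:03d}" for i in range(1, N_CHANNELS + 1)]
RECORD_COLUMNS = [
    "dosimeter_id",
    "reader_id",
    "element",
    "read_date",
    "prev_read_date",
    "dose_mrem",
    "ecc",
] + CHANNEL_COLUMNS


def records_to_frame(records: Sequence[DosimeterRecord], labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Flatten records to one row per element in the CSV dialect."""
    rows = []
    for k, rec in enumerate(records):
        for e in range(rec.n_elements):
            row = {
                "dosimeter_id": rec.dosimeter_id,
                "reader_id": rec.reader_id,
                "element": e + 1,
                "read_date": rec.read_date.isoformat() if rec.read_date else "",
                "prev_read_date": rec.previous_read_date.isoformat() if rec.previous_read_date else "",
                "dose_mrem": rec.element_doses[e],
                "ecc": rec.ecc[e],
            }
            row.update(dict(zip(CHANNEL_COLUMNS, rec.curves[e].channels)))
            if labels is not None:
                row["label"] = labels[k]
            rows.append(row)
    cols = RECORD_COLUMNS + (["label"] if labels is not None else [])
    return pd.DataFrame(rows, columns=cols)


def _parse_date(s) -> Optional[_dt.date]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    return _dt.date.fromisoformat(str(s))


def frame_to_records(df: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frame`; element rows grouped by dosimeter."""
    records = []
    for did, group in df.groupby("dosimeter_id", sort=False):
        group = group.sort_values("element")
        curves = tuple(GlowCurve(row[CHANNEL_COLUMNS].to_numpy(dtype=float)) for _, row in group.iterrows())
        first = group.iloc[0]
        records.append(
            DosimeterRecord(
                dosimeter_id=str(did),
                reader_id=str(first["reader_id"]),
                curves=curves,
                element_doses=tuple(group["dose_mrem"].astype(float)),
                read_date=_parse_date(first["read_date"]),
                previous_read_date=_parse_date(first["prev_read_date"]),
                ecc=tuple(group["ecc"].astype(float)),
            )
        )
    return records


def write_records_csv(records, path, labels=None) -> None:
    # repr keeps every float bit-exact through the round trip
    records_to_frame(records, labels).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_records_csv(path) -> list:
    return frame_to_records(
        pd.read_csv(path, keep_default_na=False, na_values=[], float_precision="round_trip")
    )


def write_records_jsonl(records, path, labels=None) -> None:
    df = records_to_frame(records, labels)
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(json.dumps(row.to_dict()) + "\n")


def read_records_jsonl(path) -> list:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return frame_to_records(pd.DataFrame(rows))
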