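"""Statistics persistence, distribution reporting, and the pipeline driver.

Every processed dosimeter leaves one append-only row in an embedded SQLite
store: curve statistics, filter pass/fail provenance, the assigned anomaly
classes and any correction.  The same store feeds the class-distribution
summaries a laboratory uses to watch for drifting reader hardware.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import ai_filter as _ai
from . import cascade as _cascade
from . import correction as _corr
from . import prefilters as _pre
from .datamodel import (
    ClassificationOutcome,
    DosimeterRecord,
    Label,
    PipelineConfig,
    RatioTable,
    Stage,
    load_config,
    read_records_csv,
    read_records_jsonl,
)

logger = logging.getLogger(__name__)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS stat_records (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    recorded_at TEXT NOT NULL,
    dosimeter_id TEXT NOT NULL,
    reader_id TEXT,
    read_date TEXT,
    stage_reached TEXT NOT NULL,
    labels TEXT NOT NULL,
    ai_probability REAL,
    spike_count INTEGER,
    corrected INTEGER,
    correction_delta REAL,
    total_dose REAL,
    curve_stats TEXT,
    ecc TEXT,
    filters TEXT
);
"""


class StatStore:
    """Append-only per-dosimeter statistics in a single SQLite file.

    Use ``":memory:"`` for throwaway stores.  Rows are queryable by date
    range, reader and class via :meth:`query`.
    """

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "StatStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def insert(self, row: dict) -> int:
        cols = ", ".join(row)
        qs = ", ".join("?" for _ in row)
        cur = self._conn.execute(f"INSERT INTO stat_records ({cols}) VALUES ({qs})", list(row.values()))
        self._conn.commit()
        return int(cur.lastrowid)

    def query(
        self,
        start: Optional[str] = None,
        end: Optional[str] = None,
        reader: Optional[str] = None,
        label: Optional[str] = None,
    ) -> pd.DataFrame:
        sql = "SELECT * FROM stat_records WHERE 1=1"
        args: list = []
        if start:
            sql += " AND read_date >= ?"
            args.append(str(start))
        if end:
            sql += " AND read_date <= ?"
            args.append(str(end))
        if reader:
            sql += " AND reader_id = ?"
            args.append(reader)
        if label:
            sql += " AND labels LIKE ?"
            args.append(f"%{label}%")
        return pd.read_sql_query(sql, self._conn, params=args)

    def __len__(self) -> int:
        return int(self._conn.execute("SELECT COUNT(*) FROM stat_records").fetchone()[0])


def record_statistics(outcome: ClassificationOutcome, record: DosimeterRecord, store: StatStore) -> int:
    """Persist one processed dosimeter; returns the stored row id."""
    row = {
        "recorded_at": _dt.datetime.now().isoformat(timespec="seconds"),
        "dosimeter_id": record.dosimeter_id,
        "reader_id": record.reader_id,
        "read_date": record.read_date.isoformat() if record.read_date else None,
        "stage_reached": outcome.stage_reached.value,
        "labels": outcome.primary_label,
        "ai_probability": outcome.ai_probability,
        "spike_count": outcome.spike_count,
        "corrected": int(outcome.corrected),
        "correction_delta": outcome.correction_delta,
        "total_dose": record.total_dose,
        "curve_stats": json.dumps(list(outcome.stats)),
        "ecc": json.dumps(list(record.ecc)),
        "filters": json.dumps(outcome.provenance, default=str),
    }
    return store.insert(row)


def summarize_distribution(
    store: StatStore,
    start: Optional[str] = None,
    end: Optional[str] = None,
    reader: Optional[str] = None,
) -> pd.Series:
    """Counts per disposition and per anomaly label.

    A_LOW and A_HIGH are counted per label, so their sum can exceed the
    number of class-A dosimeters (dual class-A curves count in both).
    An empty query yields an empty table.
    """
    df = store.query(start=start, end=end, reader=reader)
    if df.empty:
        return pd.Series(dtype=int)
    counts: dict = {}
    for stage in (Stage.BELOW_REPORTING, Stage.AI_NORMAL, Stage.MANUAL_REVIEW_RATIO_FAIL):
        n = int((df["stage_reached"] == stage.value).sum())
        if n:
            counts[stage.value] = n
    classified = df[df["stage_reached"] == Stage.CLASSIFIED.value]
    for lab in Label:
        n = int(classified["labels"].str.split("|").apply(lambda ls: lab.value in ls).sum())
        if n:
            counts[lab.value] = n
    return pd.Series(counts, dtype=int)


@dataclass
class PipelineResult:
    outcomes: list
    quarantined: list  # (dosimeter_id, error message)
    stage_log: list  # one dict per stage: name, n_in, n_out
    summary: pd.Series

    @property
    def outcome_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            rows.append(
                {
                    "dosimeter_id": o.dosimeter_id,
                    "stage_reached": o.stage_reached.value,
                    "labels": o.primary_label,
                    "ai_probability": o.ai_probability,
                    "spike_count": o.spike_count,
                    "corrected": o.corrected,
                    "correction_delta": o.correction_delta,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "dosimeter_id",
                "stage_reached",
                "labels",
                "ai_probability",
                "spike_count",
                "corrected",
                "correction_delta",
            ],
        )


def _process_record(
    record: DosimeterRecord,
    config: PipelineConfig,
    model: Optional[_ai.NormalCurveFilter],
    table: RatioTable,
) -> ClassificationOutcome:
    """Run one dosimeter through every stage; returns its terminal outcome."""
    prov: dict = {}
    stats = tuple(c.stats() for c in record.curves)

    bgd = _pre.compute_background(record.previous_read_date, record.read_date, config.RadiationPerWeek)
    prov["bgd_mrem"] = bgd.bgd
    rec = _pre.subtract_background(record, bgd)

    low = _pre.low_dose_filter(rec, config)
    prov["low_dose"] = {"total": low.total, "zeroed_elements": list(low.zeroed_elements)}
    if low.filtered_out:
        return ClassificationOutcome(
            dosimeter_id=record.dosimeter_id,
            stage_reached=Stage.BELOW_REPORTING,
            stats=stats,
            provenance=prov,
        )

    # AI filter: a dosimeter is normal only if every element curve is
    ai_prob: Optional[float] = None
    suspected = list(range(rec.n_elements))
    if config.bUseAI and model is not None:
        probs = [float(model.predict_proba_normal([c])[0]) for c in rec.curves]
        ai_prob = min(probs)
        prov["ai_probabilities"] = probs
        suspected = [i for i, p in enumerate(probs) if p <= config.ai_probability_threshold]
        if not suspected:
            return ClassificationOutcome(
                dosimeter_id=record.dosimeter_id,
                stage_reached=Stage.AI_NORMAL,
                ai_probability=ai_prob,
                stats=stats,
                provenance=prov,
            )

    decision, details = _pre.prefilter_dosimeter(rec, config, table)
    prov["ratio_filter"] = details
    if decision == "manual_review":
        return ClassificationOutcome(
            dosimeter_id=record.dosimeter_id,
            stage_reached=Stage.MANUAL_REVIEW_RATIO_FAIL,
            ai_probability=ai_prob,
            stats=stats,
            provenance=prov,
        )

    # classify the first suspected element's curve
    target = suspected[0]
    res = _cascade.classify(rec.curves[target], config)
    prov["cascade"] = dict(res.trace, element=target + 1)

    corrected = False
    delta = 0.0
    if res.labels and not (res.labels - _corr.A_LABELS):
        _, proposal = _corr.correct_class_a(
            rec.curves[target], res.labels, config, dosimeter_id=record.dosimeter_id
        )
        automated = config.bFullAutomated and rec.total_dose <= config.ManualReviewThreshold
        proposal = _corr.apply_or_suggest(proposal, automated)
        corrected = proposal.status == "applied"
        delta = proposal.delta
        prov["correction"] = {
            "status": proposal.status,
            "dose_before": proposal.dose_before,
            "dose_after": proposal.dose_after,
        }

    return ClassificationOutcome(
        dosimeter_id=record.dosimeter_id,
        stage_reached=Stage.CLASSIFIED,
        labels=res.labels,
        ai_probability=ai_prob,
        spike_count=res.spike_report.count,
        corrected=corrected,
        correction_delta=delta,
        stats=stats,
        provenance=prov,
    )


def run_pipeline(
    records,
    config: Optional[PipelineConfig] = None,
    model: Optional[_ai.NormalCurveFilter] = None,
    store: Optional[StatStore] = None,
    table: Optional[RatioTable] = None,
) -> PipelineResult:
    """Drive every stage over a batch of dosimeter records.

    ``records`` may be a list of :class:`DosimeterRecord` or a path to a
    records CSV/JSONL file.  Malformed records are quarantined (with their
    error) and the run continues; input count always equals quarantined
    plus terminal dispositions.
    """
    config = config or PipelineConfig()
    if isinstance(records, (str,)) or hasattr(records, "__fspath__"):
        path = str(records)
        records = read_records_jsonl(path) if path.endswith(".jsonl") else read_records_csv(path)
    table = table or RatioTable.default()
    if model is None and config.bUseAI and config.training_model_file:
        try:
            model = _ai.load_model(config.training_model_file)
        except (OSError, ValueError):
            logger.warning("AI model %r not found; AI filter bypassed", config.training_model_file)

    outcomes: list = []
    quarantined: list = []
    for rec in records:
        try:
            outcomes.append(_process_record(rec, config, model, table))
        except Exception as exc:  # quarantine, keep going
            did = getattr(rec, "dosimeter_id", "<unknown>")
            logger.warning("quarantined dosimeter %s: %s", did, exc)
            quarantined.append((did, str(exc)))

    if store is not None:
        by_id = {o.dosimeter_id: o for o in outcomes}
        for rec in records:
            o = by_id.get(getattr(rec, "dosimeter_id", None))
            if o is not None:
                record_statistics(o, rec, store)

    stage_counts = {s: sum(1 for o in outcomes if o.stage_reached is s) for s in Stage}
    n_in = len(records)
    stage_log = [
        {"stage": "input", "n_in": n_in, "n_out": n_in - len(quarantined), "quarantined": len(quarantined)},
        {"stage": "low_dose_filter", "n_in": n_in - len(quarantined),
         "n_out": n_in - len(quarantined) - stage_counts[Stage.BELOW_REPORTING]},
        {"stage": "ai_filter", "n_in": n_in - len(quarantined) - stage_counts[Stage.BELOW_REPORTING],
         "n_out": stage_counts[Stage.CLASSIFIED] + stage_counts[Stage.MANUAL_REVIEW_RATIO_FAIL]},
        {"stage": "ratio_filter",
         "n_in": stage_counts[Stage.CLASSIFIED] + stage_counts[Stage.MANUAL_REVIEW_RATIO_FAIL],
         "n_out": stage_counts[Stage.CLASSIFIED]},
    ]
    for line in stage_log:
        logger.info("%s", json.dumps(line))

    counts: dict = {}
    for s in (Stage.BELOW_REPORTING, Stage.AI_NORMAL, Stage.MANUAL_REVIEW_RATIO_FAIL):
        if stage_counts[s]:
            counts[s.value] = stage_counts[s]
    for lab in Label:
        n = sum(1 for o in outcomes if lab in o.labels)
        if n:
            counts[lab.value] = n
    summary = pd.Series(counts, dtype=int)
    return PipelineResult(outcomes=outcomes, quarantined=quarantined, stage_log=stage_log, summary=summary)
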