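import collections
import dataclasses
import datetime as dt

import numpy as np
import pytest

from glowcurve_qc.datamodel import (
    ClassificationOutcome,
    DosimeterRecord,
    GlowCurve,
    Label,
    PipelineConfig,
    Stage,
)
from glowcurve_qc.reporting import (
    StatStore,
    record_statistics,
    run_pipeline,
    summarize_distribution,
)
from glowcurve_qc.simulate import simulate_records


def make_record(doses, did="d1"):
    curves = tuple(GlowCurve(np.full(200, 10.0)) for _ in doses)
    return DosimeterRecord(
        did, "R1", curves, tuple(doses),
        read_date=dt.date(2024, 3, 1), previous_read_date=dt.date(2024, 2, 1),
    )


class TestStatStore:
    def test_classified_row_is_fully_populated(self):
        rec = make_record([30, 30, 30])
        outcome = ClassificationOutcome(
            "d1", Stage.CLASSIFIED, labels={Label.A_LOW}, ai_probability=0.2,
            spike_count=1, stats=tuple(c.stats() for c in rec.curves),
        )
        with StatStore() as store:
            rid = record_statistics(outcome, rec, store)
            df = store.query()
        assert rid == 1 and len(df) == 1
        row = df.iloc[0]
        assert row["labels"] == "A_LOW" and row["stage_reached"] == "classified"
        assert "median" in row["curve_stats"]

    def test_below_reporting_row_has_no_labels(self):
        rec = make_record([1, 1, 1])
        outcome = ClassificationOutcome("d1", Stage.BELOW_REPORTING)
        with StatStore() as store:
            record_statistics(outcome, rec, store)
            df = store.query()
        assert df.iloc[0]["labels"] == ""

    def test_query_filters(self):
        with StatStore() as store:
            for k, reader in enumerate(["R1", "R2", "R1"]):
                rec = dataclasses.replace(make_record([30, 30, 30], did=f"d{k}"), reader_id=reader)
                record_statistics(ClassificationOutcome(f"d{k}", Stage.AI_NORMAL), rec, store)
            assert len(store.query(reader="R1")) == 2
            assert len(store.query(start="2024-03-01", end="2024-03-01")) == 3
            assert len(store.query(start="2024-04-01")) == 0


class TestSummarizeDistribution:
    def test_all_below_threshold(self):
        with StatStore() as store:
            for k in range(10):
                record_statistics(
                    ClassificationOutcome(f"d{k}", Stage.BELOW_REPORTING), make_record([1, 1, 1], f"d{k}"), store
                )
            summary = summarize_distribution(store)
        assert summary.to_dict() == {"below_reporting": 10}

    def test_dual_a_counts_per_label(self):
        # 4 single A_LOW + 3 dual A_LOW/A_HIGH: label counts sum to 4 + 2*3
        with StatStore() as store:
            for k in range(4):
                record_statistics(
                    ClassificationOutcome(f"s{k}", Stage.CLASSIFIED, labels={Label.A_LOW}),
                    make_record([30, 30, 30], f"s{k}"), store,
                )
            for k in range(3):
                record_statistics(
                    ClassificationOutcome(f"b{k}", Stage.CLASSIFIED, labels={Label.A_LOW, Label.A_HIGH}),
                    make_record([30, 30, 30], f"b{k}"), store,
                )
            summary = summarize_distribution(store)
        assert summary["A_LOW"] + summary["A_HIGH"] == 7 + 3

    def test_empty_store_gives_empty_table(self):
        with StatStore() as store:
            assert summarize_distribution(store).empty


class TestRunPipeline:
    def test_empty_input_succeeds(self, config):
        result = run_pipeline([], config=config)
        assert result.outcomes == [] and result.quarantined == []

    def test_conservation_and_determinism(self, trained_filter, config):
        records, _ = simulate_records(60, seed=3)
        r1 = run_pipeline(records, config=config, model=trained_filter)
        r2 = run_pipeline(records, config=config, model=trained_filter)
        assert len(r1.outcomes) + len(r1.quarantined) == 60
        assert r1.outcome_frame.equals(r2.outcome_frame)

    def test_disposition_counts_match_injected_mix(self, trained_filter, config):
        records, labels = simulate_records(120, seed=11, anomalous_fraction=0.4)
        result = run_pipeline(records, config=config, model=trained_filter)
        truth = collections.Counter(labels)
        got = result.summary.to_dict()
        assert got.get("below_reporting", 0) == truth["BELOW"]
        # every injected anomaly class is recovered at least at 90% at batch level
        for lab in ("A_LOW", "A_HIGH", "C_LOW", "C_HIGH", "D"):
            if truth[lab]:
                assert got.get(lab, 0) >= 0.9 * truth[lab]

    def test_ai_bypass_sends_all_retained_curves_to_cascade(self, config):
        records, _ = simulate_records(30, seed=4)
        cfg = dataclasses.replace(config, bUseAI=False)
        result = run_pipeline(records, config=cfg, model=None)
        assert "ai_normal" not in result.summary.index
        assert all(o.ai_probability is None for o in result.outcomes)

    def test_malformed_record_is_quarantined(self, trained_filter, config):
        # dose says "exposed" but the curve is empty: feature extraction
        # cannot work and the record must be quarantined, not crash the run
        bad = DosimeterRecord(
            "bad", "R1", tuple(GlowCurve(np.zeros(200)) for _ in range(3)), (100.0, 100.0, 100.0),
            read_date=dt.date(2024, 3, 1), previous_read_date=dt.date(2024, 2, 1),
        )
        records, _ = simulate_records(5, seed=6)
        result = run_pipeline(records + [bad], config=config, model=trained_filter)
        assert [q[0] for q in result.quarantined] == ["bad"]
        assert len(result.outcomes) == 5

    def test_stats_store_records_every_disposition(self, trained_filter, config):
        records, _ = simulate_records(40, seed=8)
        with StatStore() as store:
            result = run_pipeline(records, config=config, model=trained_filter, store=store)
            assert len(store) == len(result.outcomes) == 40
            summary = summarize_distribution(store)
        # every dosimeter contributes at least one count (dual-A contributes two)
        assert summary.sum() >= 40

    def test_automated_correction_applies_for_class_a(self, trained_filter, config):
        cfg = dataclasses.replace(config, bFullAutomated=True, ManualReviewThreshold=1e9)
        records, labels = simulate_records(100, seed=13, anomalous_fraction=0.5,
                                           class_mix={"A_LOW": 1, "A_HIGH": 1})
        result = run_pipeline(records, config=cfg, model=trained_filter)
        a_outcomes = [o for o in result.outcomes if o.labels and not (o.labels - {Label.A_LOW, Label.A_HIGH})]
        assert a_outcomes and all(o.corrected for o in a_outcomes)
        assert all(o.correction_delta > 0 for o in a_outcomes)
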