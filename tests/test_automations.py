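"""Signals, gated auto-merge, scheduler, and the no-click chain."""

from __future__ import annotations

import random
import threading
from pathlib import Path

import pytest

from biobank.automations import MergeSpec, Scheduler, Signal
from biobank.errors import DuplicateSignalError
from biobank.executors import LocalExecutor
from biobank.fixtures import CohortSpec, make_cohort, make_raw_files

from conftest import import_cohort


def _analysis(bank, app, experiments, status="SUCCEEDED", project=None):
    """Persist an analysis record directly with a legal status walk."""
    rec = bank.store.create_record("analysis", {
        "application": app.identity_map,
        "targets": [e["system_id"] for e in experiments],
        "projects": [project["system_id"]] if project else [],
        "individuals": [],
        "status": "CREATED",
    })
    walk = {"CREATED": [], "STAGED": ["STAGED"],
            "SUBMITTED": ["STAGED", "SUBMITTED"],
            "STARTED": ["STAGED", "SUBMITTED", "STARTED"],
            "SUCCEEDED": ["STAGED", "SUBMITTED", "STARTED", "SUCCEEDED"],
            "FAILED": ["STAGED", "SUBMITTED", "STARTED", "FAILED"]}[status]
    for step in walk:
        rec = bank.store.update_record("analysis", rec["system_id"],
                                       {"status": step})
    return rec


class TestSignals:
    def test_duplicate_name_rejected(self, bank):
        sig = Signal("s", lambda *a: True, lambda *a: None)
        bank.signals.register(sig)
        with pytest.raises(DuplicateSignalError):
            bank.signals.register(Signal("s", lambda *a: True,
                                         lambda *a: None))

    def test_no_matching_signal_gives_empty_outcomes(self, bank):
        outcomes = bank.signals.dispatch({"kind": "experiment"}, None,
                                         "IMPORTED")
        assert outcomes == []

    def test_unregistered_signal_does_not_fire(self, bank):
        fired = []
        bank.signals.register(Signal("s", lambda *a: True,
                                     lambda *a: fired.append(1)))
        bank.signals.unregister("s")
        bank.signals.dispatch({"kind": "experiment"}, None, "IMPORTED")
        assert fired == []

    def test_import_signal_autocreates_qc_analysis(self, bank, project,
                                                   cohort, toy_apps,
                                                   tmp_path):
        gc = toy_apps["gc_qc"]

        def deploy_qc(record, old, new):
            tup = bank.tuple_for([record])
            return bank.apps.get_or_create_analysis(gc, tup)

        bank.signals.register(Signal(
            "import->qc",
            lambda rec, old, new: rec.get("kind") == "experiment"
            and new == "IMPORTED",
            deploy_qc))
        import_cohort(bank, cohort, tmp_path)
        analyses = bank.db.all("analysis")
        assert len(analyses) == len(cohort.experiments)

    def test_failing_signal_contained(self, bank, cohort, tmp_path):
        """A raising signal is reported, does not corrupt the record's
        status, and does not block later signals."""
        fired = []

        def boom(record, old, new):
            raise RuntimeError("signal exploded")

        bank.signals.register(Signal(
            "boom", lambda rec, old, new: new == "IMPORTED", boom))
        bank.signals.register(Signal(
            "after", lambda rec, old, new: new == "IMPORTED",
            lambda rec, old, new: fired.append(rec["custom_id"])))
        import_cohort(bank, cohort, tmp_path)
        assert len(fired) == len(cohort.experiments)
        assert all(e["import_status"] == "IMPORTED"
                   for e in bank.db.all("experiment"))
        note = bank.signals.notifications[0]
        assert "signal exploded" in note["error"]
        assert "restart" in note["instructions"]

    def test_chained_signal_fires_on_success_not_failure(self, bank,
                                                         imported_cohort,
                                                         toy_apps):
        gc, rc = toy_apps["gc_qc"], toy_apps["read_count"]
        chained = []

        def deploy_next(record, old, new):
            tup = bank.tuple_for(record["targets"])
            out = bank.apps.get_or_create_analysis(rc, tup)
            chained.append(out)
            return out

        bank.signals.register(Signal(
            "qc-success->read-count",
            lambda rec, old, new: rec.get("kind") == "analysis"
            and rec["application"] == gc.identity_map and new == "SUCCEEDED",
            deploy_next))
        exps = imported_cohort.experiments
        ok, _ = bank.apps.get_or_create_analysis(
            gc, bank.tuple_for(exps[:1]))
        bad, _ = bank.apps.get_or_create_analysis(
            gc, bank.tuple_for(exps[1:2]))
        for step in ("STAGED", "SUBMITTED", "STARTED"):
            ok = bank.apps.set_status(ok, step)
            bad = bank.apps.set_status(bad, step)
        bank.apps.set_status(bad, "FAILED")
        assert chained == []
        # toy results are parsed on success; write them first
        out = Path(ok["storage_url"]) / "results"
        out.mkdir(parents=True, exist_ok=True)
        (out / "gc_qc.txt").write_text("gc_fraction=0.5\n")
        bank.apps.set_status(ok, "SUCCEEDED")
        assert len(chained) == 1


class TestMergeGating:
    def test_gate_blocks_while_analyses_ongoing(self, bank, project,
                                                imported_cohort, toy_apps):
        gc = toy_apps["gc_qc"]
        spec = MergeSpec(gc, "PROJECT")
        exps = imported_cohort.experiments
        _analysis(bank, gc, exps[:1], "SUCCEEDED", project)
        _analysis(bank, gc, exps[1:2], "STARTED", project)
        assert bank.merger.should_merge(spec, project) is False

    def test_failed_is_terminal_and_does_not_block(self, bank, project,
                                                   imported_cohort,
                                                   toy_apps):
        gc = toy_apps["gc_qc"]
        spec = MergeSpec(gc, "PROJECT")
        exps = imported_cohort.experiments
        statuses = ["SUCCEEDED", "SUCCEEDED", "FAILED"]
        for exp, status in zip(exps, statuses):
            _analysis(bank, gc, [exp], status, project)
        # oracle: census against the stated predicate
        census = [a["status"] for a in bank.db.all("analysis")]
        assert any(s == "SUCCEEDED" for s in census)
        assert not any(s in ("CREATED", "STAGED", "SUBMITTED", "STARTED")
                       for s in census)
        assert bank.merger.should_merge(spec, project) is True

    def test_no_analyses_no_merge(self, bank, project, toy_apps):
        assert bank.merger.should_merge(
            MergeSpec(toy_apps["gc_qc"], "PROJECT"), project) is False

    def test_merge_rows_one_per_analysis(self, bank, project,
                                         imported_cohort, toy_apps):
        gc = toy_apps["gc_qc"]
        for exp in imported_cohort.experiments[:3]:
            rec = _analysis(bank, gc, [exp], "STARTED", project)
            rec = bank.store.update_record(
                "analysis", rec["system_id"],
                {"status": "SUCCEEDED", "results": {"gc_fraction": 0.5}})
        merged = bank.merger.run_merge(MergeSpec(gc, "PROJECT"), project)
        table = Path(merged["results"]["merged_table"]).read_text()
        assert len(table.splitlines()) == 4  # header + 3 rows

    def test_new_success_re_merges_and_archives_old(self, bank, project,
                                                    imported_cohort,
                                                    toy_apps):
        gc = toy_apps["gc_qc"]
        spec = MergeSpec(gc, "PROJECT")
        for exp in imported_cohort.experiments[:3]:
            rec = _analysis(bank, gc, [exp], "STARTED", project)
            bank.store.update_record(
                "analysis", rec["system_id"],
                {"status": "SUCCEEDED", "results": {"gc_fraction": 0.5}})
        first = bank.merger.run_merge(spec, project)
        rec = _analysis(bank, gc, [imported_cohort.experiments[3]],
                        "STARTED", project)
        bank.store.update_record(
            "analysis", rec["system_id"],
            {"status": "SUCCEEDED", "results": {"gc_fraction": 0.9}})
        second = bank.merger.run_merge(spec, project)
        assert second["system_id"] != first["system_id"]
        table = Path(second["results"]["merged_table"]).read_text()
        assert len(table.splitlines()) == 5
        old = bank.db.get("analysis", first["system_id"])
        assert old["superseded"]
        legacy = list(Path(first["storage_url"]).glob("__legacy__/*"))
        assert len(legacy) == 1

    def test_unchanged_succeeded_set_does_not_rerun(self, bank, project,
                                                    imported_cohort,
                                                    toy_apps):
        gc = toy_apps["gc_qc"]
        spec = MergeSpec(gc, "PROJECT")
        rec = _analysis(bank, gc, imported_cohort.experiments[:1],
                        "STARTED", project)
        bank.store.update_record(
            "analysis", rec["system_id"],
            {"status": "SUCCEEDED", "results": {"gc_fraction": 0.5}})
        first = bank.merger.run_merge(spec, project)
        second = bank.merger.run_merge(spec, project)
        assert second["system_id"] == first["system_id"]
        assert len(bank.merger.executed) == 1

    def test_concurrent_merge_no_ops(self, bank, project, imported_cohort,
                                     toy_apps):
        gc = toy_apps["gc_qc"]
        gate = threading.Event()
        release = threading.Event()

        def slow_hook(app, analyses, outdir):
            gate.set()
            release.wait(timeout=5)
            path = Path(outdir) / "merged.tsv"
            path.write_text("analysis\n")
            return {"merged_table": str(path)}

        spec = MergeSpec(gc, "PROJECT", merge_hook=slow_hook)
        rec = _analysis(bank, gc, imported_cohort.experiments[:1],
                        "STARTED", project)
        bank.store.update_record(
            "analysis", rec["system_id"],
            {"status": "SUCCEEDED", "results": {"gc_fraction": 0.5}})
        results = []
        t = threading.Thread(
            target=lambda: results.append(bank.merger.run_merge(spec,
                                                                project)))
        t.start()
        gate.wait(timeout=5)
        assert bank.merger.run_merge(spec, project) is None  # in flight
        release.set()
        t.join(timeout=5)
        assert results[0] is not None
        assert len(bank.merger.executed) == 1

    def test_randomized_transition_replay_respects_gate(self, bank, project,
                                                        imported_cohort,
                                                        toy_apps):
        """Replaying random status logs, merges only run when the gate
        predicate holds at that instant (checked inside the hook)."""
        gc = toy_apps["gc_qc"]
        rng = random.Random(17)
        gate_states = []

        def checking_hook(app, analyses, outdir):
            census = [a["status"] for a in bank.db.all("analysis")
                      if a["application"] == gc.identity_map
                      and not a.get("project_level")
                      and not a.get("superseded")]
            gate_states.append(
                any(s == "SUCCEEDED" for s in census)
                and not any(s in ("CREATED", "STAGED", "SUBMITTED",
                                  "STARTED") for s in census))
            path = Path(outdir) / "merged.tsv"
            path.write_text("analysis\n" + "\n".join(
                a["system_id"] for a in analyses))
            return {"merged_table": str(path)}

        spec = MergeSpec(gc, "PROJECT", merge_hook=checking_hook)
        signal = bank.merger.make_signal(spec)
        bank.signals.register(signal)
        pending = []
        for exp in imported_cohort.experiments:
            rec = bank.store.create_record("analysis", {
                "application": gc.identity_map,
                "targets": [exp["system_id"]],
                "projects": [project["system_id"]],
                "status": "CREATED",
            })
            pending.append((rec["system_id"],
                            ["STAGED", "SUBMITTED", "STARTED",
                             rng.choice(["SUCCEEDED", "FAILED"])]))
        while pending:
            idx = rng.randrange(len(pending))
            sid, steps = pending[idx]
            step = steps.pop(0)
            rec = bank.db.get("analysis", sid)
            old = rec["status"]
            rec = bank.store.update_record("analysis", sid,
                                           {"status": step,
                                            "results": {"gc_fraction": 0.1}
                                            if step == "SUCCEEDED" else {}})
            bank.signals.dispatch(rec, old, step)
            if not steps:
                pending.pop(idx)
        assert gate_states and all(gate_states)
        # at-most-once per quiescent state: merged input sets all distinct
        merges = [a for a in bank.db.all("analysis") if a.get("project_level")]
        input_sets = [tuple(m["config_snapshot"]["merged_inputs"])
                      for m in merges]
        assert len(set(input_sets)) == len(input_sets)


class TestScheduler:
    def test_at_most_once_per_period(self):
        sched = Scheduler()
        runs = []
        sched.schedule_task(10.0, lambda: runs.append(1))
        sched.tick(now=0.0)
        sched.tick(now=5.0)
        assert len(runs) == 1
        sched.tick(now=10.0)
        assert len(runs) == 2

    def test_cancel_stops_invocations(self):
        sched = Scheduler()
        runs = []
        handle = sched.schedule_task(1.0, lambda: runs.append(1))
        sched.tick(now=0.0)
        sched.cancel(handle)
        sched.tick(now=5.0)
        assert len(runs) == 1

    def test_raising_action_logged_and_schedule_continues(self):
        sched = Scheduler()
        runs = []

        def bad():
            raise ValueError("task broke")

        sched.schedule_task(1.0, bad)
        sched.schedule_task(1.0, lambda: runs.append(1))
        sched.tick(now=0.0)
        sched.tick(now=2.0)
        assert len(runs) == 2
        assert len(sched.errors) == 2
        assert "task broke" in sched.errors[0][1]


class TestNoClickChain:
    def test_end_to_end_chain_produces_merged_report(self, bank, tmp_path,
                                                     toy_apps):
        """batch register + import with signals import→GC→paired-diff→merge:
        the final merged table appears with no manual step in between."""
        gc, pdiff = toy_apps["gc_qc"], toy_apps["paired_diff"]
        executor = LocalExecutor()
        project = bank.get_or_create_project("CHAIN")

        def deploy_gc(record, old, new):
            return bank.apps.run(gc, [bank.tuple_for([record])], executor)

        def deploy_paired(record, old, new):
            exps = [e for e in bank.db.all("experiment")
                    if e["import_status"] == "IMPORTED"]
            plan = bank.apps.plan_tuples(pdiff, exps, "PAIRED_BY_INDIVIDUAL")
            return bank.apps.run(pdiff, plan.tuples, executor)

        bank.signals.register(Signal(
            "import->gc",
            lambda rec, old, new: rec.get("kind") == "experiment"
            and new == "IMPORTED", deploy_gc))
        bank.signals.register(Signal(
            "gc-success->paired",
            lambda rec, old, new: rec.get("kind") == "analysis"
            and rec["application"] == gc.identity_map
            and new == "SUCCEEDED", deploy_paired))
        bank.signals.register(bank.merger.make_signal(
            MergeSpec(pdiff, "PROJECT")))

        cohort = make_cohort(bank.store, CohortSpec(2, paired=True, seed=8),
                             project)
        deposit = make_raw_files(cohort.experiments, tmp_path / "dep",
                                 reads_per_file=10, seed=8)
        scan = bank.lake.scan_and_match(deposit, cohort.experiments)
        bank.lake.import_data(scan, actor="admin")
        bank.apps.wait(timeout=120)

        merges = [a for a in bank.db.all("analysis")
                  if a.get("project_level") and not a.get("superseded")]
        assert len(merges) == 1
        table = Path(merges[0]["results"]["merged_table"]).read_text()
        # one row per paired-diff analysis (2 individuals -> 2 pairs)
        assert len(table.splitlines()) == 3
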