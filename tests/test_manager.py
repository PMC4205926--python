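"""Simulation manager: expansion, serialization, batching, schema, storage."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qspsim.errors import (
    ConfigurationError, IntegrityError, SerializationError, ValidationError,
)
from qspsim.manager import (
    ExposedParameterSchema, SchemaControl, TaskFailure, expand_tasks,
    load_results, parse_task, run_batch, serialize_task, store_results,
    validate_schema,
)
from qspsim.plugins import (
    build_metabolic_plugin, build_toy_plugin, metabolic_parameter_listing,
)
from qspsim.protocols import Protocol, build_ogtt, standard_meals
from qspsim.results import TimeSeriesResult
from qspsim.vpatients import ValueSet, VirtualPatient


@pytest.fixture(scope="module")
def toy_plugin():
    return build_toy_plugin()


@pytest.fixture()
def toy_proto():
    return Protocol(duration_days=1, outputs=(), output_interval=0.5,
                    run_in_days=0)


def _vps(n):
    return [VirtualPatient(id=f"vp{i}", phenotypes=("toy",),
                           overrides={"y0": float(i + 1)}) for i in range(n)]


def _opt(label, **values):
    return ValueSet(group="therapy", label=label, values=values)


class TestExpandTasks:
    def test_three_vps_one_therapy_three_tasks(self, toy_plugin, toy_proto):
        tasks = expand_tasks(_vps(3), [[_opt("a", k_decay=0.3)]], "crossed",
                             toy_proto, ("y",), toy_plugin.parameters)
        assert len(tasks) == 3

    def test_three_vps_two_therapies_crossed_six_tasks(self, toy_plugin,
                                                       toy_proto):
        opts = [[_opt("a", k_decay=0.3), _opt("b", k_decay=0.6)]]
        tasks = expand_tasks(_vps(3), opts, "crossed", toy_proto, ("y",),
                             toy_plugin.parameters)
        assert len(tasks) == 6
        # VP-major, option-lexicographic order
        assert [(t.vp_id, t.therapy_labels) for t in tasks[:2]] == \
            [("vp0", ("a",)), ("vp0", ("b",))]

    def test_combination_mode_three_tasks(self, toy_plugin, toy_proto):
        opts = [[_opt("a", k_decay=0.3)], [_opt("b", y0=5.0)]]
        tasks = expand_tasks(_vps(3), opts, "combination", toy_proto, ("y",),
                             toy_plugin.parameters)
        assert len(tasks) == 3
        assert tasks[0].therapy_labels == ("a", "b")

    def test_combination_conflict_names_parameter(self, toy_plugin,
                                                  toy_proto):
        opts = [[_opt("a", k_decay=0.3)], [_opt("b", k_decay=0.6)]]
        with pytest.raises(ConfigurationError, match="k_decay"):
            expand_tasks(_vps(2), opts, "combination", toy_proto, ("y",),
                         toy_plugin.parameters)

    @given(n_vps=st.integers(0, 5),
           sizes=st.lists(st.integers(1, 4), max_size=3))
    def test_crossed_count_matches_cartesian_oracle(self, n_vps, sizes,
                                                    toy_plugin):
        proto = Protocol(duration_days=1, outputs=(), output_interval=0.5,
                         run_in_days=0)
        opts = [[_opt(f"o{i}-{j}", k_decay=0.1 * (j + 1))
                 for j in range(k)] for i, k in enumerate(sizes)]
        tasks = expand_tasks(_vps(n_vps), opts, "crossed", proto, ("y",),
                             toy_plugin.parameters)
        expected = n_vps * int(np.prod(sizes)) if sizes else n_vps
        assert len(tasks) == expected

    def test_task_id_deterministic_for_identical_content(self, toy_plugin,
                                                         toy_proto):
        a = expand_tasks(_vps(1), [[_opt("a", k_decay=0.3)]], "crossed",
                         toy_proto, ("y",), toy_plugin.parameters)
        b = expand_tasks(_vps(1), [[_opt("a", k_decay=0.3)]], "crossed",
                         toy_proto, ("y",), toy_plugin.parameters)
        assert a[0].task_id == b[0].task_id


class TestTaskDocuments:
    def test_serialize_parse_round_trip(self, toy_plugin, toy_proto):
        task = expand_tasks(_vps(1), [[_opt("a", k_decay=0.25)]], "crossed",
                            toy_proto, ("y",), toy_plugin.parameters)[0]
        doc = serialize_task(task, toy_plugin)
        back = parse_task(doc)
        assert back == task
        assert back.task_id == task.task_id

    def test_one_parameter_change_one_line_diff(self, toy_plugin, toy_proto):
        t1, t2 = expand_tasks(
            _vps(1), [[_opt("a", k_decay=0.25), _opt("b", k_decay=0.5)]],
            "crossed", toy_proto, ("y",), toy_plugin.parameters)
        d1 = serialize_task(t1).splitlines()
        d2 = serialize_task(t2).splitlines()
        param_diffs = [(a, b) for a, b in zip(d1, d2)
                       if a != b and "\t" in a and not a.startswith("label")]
        assert len(param_diffs) == 1
        assert param_diffs[0][0].startswith("k_decay\t")

    def test_missing_parameter_named(self, toy_plugin, toy_proto):
        task = expand_tasks(_vps(1), [[_opt("a", k_decay=0.25)]], "crossed",
                            toy_proto, ("y",), toy_plugin.parameters)[0]
        broken = type(task)(model_id=task.model_id,
                            assignment={"y0": 1.0},  # k_decay missing
                            protocol=task.protocol,
                            output_spec=task.output_spec)
        with pytest.raises(SerializationError, match="k_decay"):
            serialize_task(broken, toy_plugin)

    def test_malformed_document_rejected(self):
        with pytest.raises(SerializationError):
            parse_task("# simulation task v1\n[model]\nid\tx\n")


class TestRunBatch:
    def test_worker_count_does_not_change_values(self, toy_plugin,
                                                 toy_proto):
        opts = [[_opt(f"k{j}", k_decay=0.1 * (j + 1)) for j in range(2)]]
        tasks = expand_tasks(_vps(3), opts, "crossed", toy_proto, ("y",),
                             toy_plugin.parameters,
                             model_id=toy_plugin.model_id)
        serial = run_batch(tasks, toy_plugin, workers=1)
        parallel = run_batch(tasks, toy_plugin, workers=4)
        for a, b in zip(serial, parallel):
            assert np.array_equal(a["y"], b["y"])
            assert a.task_id == b.task_id

    def test_empty_batch(self, toy_plugin):
        assert run_batch([], toy_plugin, workers=2) == []

    def test_failures_isolated_per_task(self, toy_plugin, toy_proto):
        tasks = expand_tasks(
            _vps(1),
            [[_opt("ok", k_decay=0.5), _opt("bad", k_decay=-1.0),
              _opt("ok2", k_decay=0.7)]],
            "crossed", toy_proto, ("y",), toy_plugin.parameters,
            model_id=toy_plugin.model_id)
        out = run_batch(tasks, toy_plugin, workers=1)
        kinds = [type(r).__name__ for r in out]
        assert kinds == ["TimeSeriesResult", "TaskFailure", "TimeSeriesResult"]
        assert "decay rate" in out[1].error

    def test_metabolic_and_toy_plugins_share_the_manager_path(self):
        """Model agnosticism: the full physiological model runs through the
        identical expansion/batch machinery as the toy fixture."""
        plugin = build_metabolic_plugin()
        vp = VirtualPatient(id="t2dm", phenotypes=("T2DM",),
                            overrides={"hepatic_insulin_sensitivity": 0.22})
        proto = Protocol(duration_days=1, meals=standard_meals(),
                         ogtts=(build_ogtt(75.0, 0),),
                         outputs=("G_plasma", "I_plasma"),
                         output_interval=0.25, run_in_days=0)
        tasks = expand_tasks([vp], [], "crossed", proto,
                             ("G_plasma", "I_plasma"), plugin.parameters,
                             model_id=plugin.model_id)
        assert len(tasks) == 1
        (res,) = run_batch(tasks, plugin, workers=1)
        assert isinstance(res, TimeSeriesResult)
        assert res["G_plasma"].max() > res["G_plasma"][0]


class TestSchema:
    def test_unknown_parameter_flagged(self, toy_plugin):
        schema = ExposedParameterSchema([
            SchemaControl("main", "nonexistent", "X", "text", "RATE", 0, 0)])
        report = validate_schema(schema, toy_plugin)
        assert any("nonexistent" in line for line in report)

    def test_duplicate_cell_flagged(self, toy_plugin):
        schema = ExposedParameterSchema([
            SchemaControl("main", "y0", "y0", "text", "DIMLESS", 0, 0),
            SchemaControl("main", "k_decay", "k", "text", "RATE", 0, 0)])
        report = validate_schema(schema, toy_plugin)
        assert any("duplicate grid cell" in line for line in report)

    def test_category_mismatch_flagged(self, toy_plugin):
        schema = ExposedParameterSchema([
            SchemaControl("main", "k_decay", "k", "text", "DOSE", 0, 0)])
        report = validate_schema(schema, toy_plugin)
        assert any("category mismatch" in line for line in report)

    def test_valid_schema_empty_report(self, toy_plugin):
        schema = ExposedParameterSchema([
            SchemaControl("main", "y0", "start", "text", "DIMLESS", 0, 0),
            SchemaControl("main", "k_decay", "rate", "text", "RATE", 0, 1)])
        assert validate_schema(schema, toy_plugin) == []

    def test_keyword_filter_matches_substring_oracle(self):
        plugin = build_metabolic_plugin()
        schema = ExposedParameterSchema()
        got = schema.keyword_filter(plugin, "meal")
        listing = metabolic_parameter_listing()
        assert got == [n for n in listing.names() if "meal" in n]
        assert "meal1_kcal" in got


class TestResultStore:
    def _batch(self, toy_plugin, toy_proto):
        tasks = expand_tasks(_vps(2), [[_opt("a", k_decay=0.4)]], "crossed",
                             toy_proto, ("y",), toy_plugin.parameters,
                             model_id=toy_plugin.model_id)
        return run_batch(tasks, toy_plugin)

    def test_store_load_round_trip(self, tmp_path, toy_plugin, toy_proto):
        results = self._batch(toy_plugin, toy_proto)
        manifest = store_results(results, tmp_path)
        back = load_results(manifest)
        assert len(back) == len(results)
        for a, b in zip(results, back):
            assert np.allclose(a["y"], b["y"], rtol=1e-10)
            assert a.task_id == b.task_id

    def test_manifest_entry_count(self, tmp_path, toy_plugin, toy_proto):
        results = self._batch(toy_plugin, toy_proto)
        manifest = store_results(results, tmp_path)
        import json
        doc = json.loads(manifest.read_text())
        assert len(doc["results"]) == len(results)

    def test_corruption_detected_and_named(self, tmp_path, toy_plugin,
                                           toy_proto):
        results = self._batch(toy_plugin, toy_proto)
        manifest = store_results(results, tmp_path)
        import json
        doc = json.loads(manifest.read_text())
        first = doc["results"][0]
        victim = tmp_path / first["file"]
        victim.write_text(victim.read_text() + "# tampered\n")
        with pytest.raises(IntegrityError, match=first["task_id"]):
            load_results(manifest)

    def test_failures_survive_the_round_trip(self, tmp_path):
        failure = TaskFailure(task_id="deadbeef", error="boom")
        manifest = store_results([failure], tmp_path)
        (back,) = load_results(manifest)
        assert isinstance(back, TaskFailure)
        assert back.task_id == "deadbeef"


class TestSubprocessAdapter:
    def test_external_process_contract(self, toy_plugin, toy_proto):
        """A task document piped through a separate interpreter process
        returns the same series as the in-process plugin."""
        import sys

        from qspsim.manager import run_task_subprocess

        task = expand_tasks(_vps(1), [[_opt("a", k_decay=0.4)]], "crossed",
                            toy_proto, ("y",), toy_plugin.parameters,
                            model_id=toy_plugin.model_id)[0]
        external = run_task_subprocess(
            task, [sys.executable, "-m", "qspsim.cli", "run-task"],
            timeout=120)
        internal = toy_plugin.run(task)
        assert np.allclose(external["y"], internal["y"], rtol=1e-10)
        assert external.task_id == task.task_id
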