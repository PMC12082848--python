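import dataclasses
import json
import threading
import time
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

import pytest

from kgexplore.examples import app_alzheimer_queryspec
from kgexplore.pipeline import NESTING_LEVELS, PlanSpec, explore
from kgexplore.sparql import (EndpointError, QueryTimeoutError, render,
                              run_remote, verify_local)
from kgexplore.sparql import _merged_graph  # loopback test server backend
from kgexplore.synth import SynthParams, focal_queryspec, generate


class TestRender:
    def test_centralized_one_subquery_structure(self, app_qspec):
        rendered = render(app_qspec, PlanSpec(nesting="one_subquery"))
        inner_selects = rendered.text.count("SELECT DISTINCT") - 1
        assert inner_selects == 1
        assert "SERVICE" not in rendered.text
        assert not rendered.uses_property_path

    @pytest.mark.parametrize("nesting, n_inner", [
        ("flat", 0), ("one_subquery", 1), ("two_subqueries", 2),
        ("three_subqueries", 3),
    ])
    def test_nesting_depth_matches_plan(self, app_qspec, nesting, n_inner):
        rendered = render(app_qspec, PlanSpec(nesting=nesting))
        assert rendered.text.count("SELECT DISTINCT") - 1 == n_inner

    def test_federated_wraps_expression_block_in_one_service(self, app_qspec):
        plan = PlanSpec(nesting="one_subquery", mode="federated",
                        expression_endpoint="https://bgee.example.org/sparql")
        rendered = render(app_qspec, plan)
        assert rendered.text.count("SERVICE <https://bgee.example.org/sparql>") == 1
        service_part = rendered.text.split("SERVICE")[1]
        assert "hasAnatomicalEntity" in service_part

    def test_closure_toggles_property_path(self, app_qspec):
        off = render(app_qspec, PlanSpec())
        on = render(dataclasses.replace(app_qspec, use_closure=True), PlanSpec())
        assert "skos:broader*" in on.text and on.uses_property_path
        assert "skos:broader*" not in off.text
        assert "FILTER(?anat = obo:UBERON_0000451)" in off.text

    def test_limit_offset_emitted_iff_set(self, app_qspec):
        plain = render(app_qspec, PlanSpec())
        assert "LIMIT" not in plain.text and "OFFSET" not in plain.text
        paged = render(dataclasses.replace(app_qspec, limit=100, offset=20), PlanSpec())
        assert "LIMIT 100" in paged.text and "OFFSET 20" in paged.text
        assert "ORDER BY" in paged.text

    def test_rendering_is_deterministic(self, app_qspec):
        plan = PlanSpec(nesting="two_subqueries")
        assert render(app_qspec, plan).text == render(app_qspec, plan).text

    def test_all_prefixes_come_from_the_namespace_table(self, app_qspec):
        from kgexplore.namespaces import default_table
        table = dict(default_table())
        for line in render(app_qspec, PlanSpec()).text.splitlines():
            if line.startswith("PREFIX"):
                _, prefix, iri = line.split()
                assert table[prefix.rstrip(":")] == iri.strip("<>")


class TestVerifyLocal:
    def test_worked_example_single_row(self, app_kg, app_qspec):
        rendered = render(app_qspec, PlanSpec(nesting="one_subquery"))
        result = verify_local(app_kg, rendered)
        assert result == explore(app_qspec, app_kg)
        assert len(result) == 1

    def test_rejects_federated_renderings(self, app_kg, app_qspec):
        plan = PlanSpec(mode="federated", expression_endpoint="http://x/sparql")
        with pytest.raises(ValueError):
            verify_local(app_kg, render(app_qspec, plan))

    def test_engine_matches_native_with_and_without_closure(self):
        kg, gt = generate(SynthParams(seed=5))
        for closure in (False, True):
            qspec = focal_queryspec(gt, use_closure=closure)
            rendered = render(qspec, PlanSpec(nesting="one_subquery"))
            assert verify_local(kg, rendered) == explore(qspec, kg)

    def test_engine_matches_native_across_nestings(self, app_kg, app_qspec):
        reference = explore(app_qspec, app_kg)
        for nesting in NESTING_LEVELS:
            rendered = render(app_qspec, PlanSpec(nesting=nesting))
            assert verify_local(app_kg, rendered) == reference

    def test_limit_bounds_engine_rows(self, synth_kg_gt):
        kg, gt = synth_kg_gt
        qspec = focal_queryspec(gt, use_closure=True, limit=3)
        rendered = render(qspec, PlanSpec(nesting="one_subquery"))
        assert len(verify_local(kg, rendered)) <= 3


# ---------------------------------------------------------------------------
# loopback SPARQL endpoint


class _LoopbackHandler(BaseHTTPRequestHandler):
    graph = None
    delay_s = 0.0

    def do_POST(self):
        length = int(self.headers.get("Content-Length", 0))
        params = urllib.parse.parse_qs(self.rfile.read(length).decode())
        query = params.get("query", [""])[0]
        time.sleep(self.delay_s)
        result = self.graph.query(query)
        bindings = []
        for sol in result:
            d = sol.asdict()
            bindings.append({k: {"type": "uri", "value": str(v)} for k, v in d.items()})
        body = json.dumps({
            "head": {"vars": [str(v) for v in result.vars]},
            "results": {"bindings": bindings},
        }).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/sparql-results+json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def log_message(self, *args):
        pass


@pytest.fixture(scope="module")
def loopback_endpoint(synth_kg_gt):
    kg, _ = synth_kg_gt
    _LoopbackHandler.graph = _merged_graph(kg)
    server = ThreadingHTTPServer(("127.0.0.1", 0), _LoopbackHandler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    yield f"http://127.0.0.1:{server.server_address[1]}/sparql"
    server.shutdown()


class TestRunRemote:
    def test_unreachable_host_signals_endpoint_error(self, app_qspec):
        rendered = render(app_qspec, PlanSpec())
        with pytest.raises(EndpointError):
            run_remote(rendered, "http://127.0.0.1:9/sparql", timeout_s=5)

    def test_slow_server_times_out(self, synth_kg_gt, loopback_endpoint):
        _, gt = synth_kg_gt
        rendered = render(focal_queryspec(gt), PlanSpec())
        _LoopbackHandler.delay_s = 1.0
        try:
            with pytest.raises(QueryTimeoutError):
                run_remote(rendered, loopback_endpoint, timeout_s=0.25)
        finally:
            _LoopbackHandler.delay_s = 0.0

    def test_loopback_rows_equal_embedded_engine(self, synth_kg_gt, loopback_endpoint):
        kg, gt = synth_kg_gt
        qspec = focal_queryspec(gt, use_closure=True)
        rendered = render(qspec, PlanSpec(nesting="one_subquery"))
        rows, elapsed = run_remote(rendered, loopback_endpoint, timeout_s=60)
        local = verify_local(kg, rendered)
        remote_keys = {(r["resource"], r["mgi"], r["humanEns"], r["anat"]) for r in rows}
        from kgexplore.namespaces import default_table
        table = default_table()
        local_keys = {(table.expand(r.bioresource), table.expand(r.mouse_gene),
                       table.expand(r.human_gene), table.expand(r.anatomical_entity))
                      for r in local}
        assert remote_keys == local_keys
        assert elapsed >= 0.0
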