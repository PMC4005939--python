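"""HTTP contract: verb/URL table, status codes, caching, datafiles."""

import io

import h5py
import numpy as np
import pytest

from ephyshub import Quantity, deserialize, serialize
from ephyshub.model import ArrayValue
from ephyshub.rest import fields_to_document


@pytest.fixture
def api(service, loaded_store):
    _, ids = loaded_store

    def call(method, path, params=None, body=None, headers=None, actor="alice"):
        return service.route_request(
            method, path, params=params, body=body, headers=headers, actor=actor
        )

    call.ids = ids
    call.service = service
    return call


class TestVerbTable:
    def test_get_single_object_returns_document(self, api):
        st_id = api.ids["st.t1.u1"]
        resp = api("GET", f"/electrophysiology/spiketrain/{st_id}/")
        assert resp.status == 200
        assert resp.body["id"] == st_id
        assert resp.body["fields"]["name"] == "trial 1 U1 spikes"
        assert resp.headers["ETag"] == resp.body["etag"]
        assert "Last-Modified" in resp.headers

    def test_post_single_updates_name_and_comment(self, api):
        st_id = api.ids["st.t1.u1"]
        resp = api(
            "POST",
            f"/electrophysiology/spiketrain/{st_id}/",
            body={"name": "renamed", "comment": "checked"},
        )
        assert resp.status == 200
        assert resp.body["fields"]["name"] == "renamed"
        assert resp.body["fields"]["comment"] == "checked"

    def test_delete_on_acl_url_is_405(self, api):
        sec_id = api.ids["protocol"]
        resp = api("DELETE", f"/metadata/section/{sec_id}/acl/")
        assert resp.status == 405
        assert "message" in resp.body

    def test_list_envelope_with_filters(self, api):
        resp = api(
            "GET", "/electrophysiology/event/", params={"label": "stimulus"}
        )
        assert resp.status == 200
        assert resp.body["total"] == 4
        assert {o["fields"]["label"] for o in resp.body["objects"]} == {"stimulus"}

    def test_create_via_collection_post(self, api):
        resp = api(
            "POST",
            "/electrophysiology/event/",
            body={
                "label": "offset",
                "time": {"value": 900, "units": "ms"},
                "segment": api.ids["seg1"],
            },
        )
        assert resp.status == 201
        assert resp.body["fields"]["time"] == {"value": 900, "units": "ms"}
        assert resp.headers["Location"] == resp.body["location"]

    def test_bulk_update_and_bulk_delete(self, api):
        resp = api(
            "POST",
            "/electrophysiology/event/",
            body={"filters": {"label": "stimulus"}, "fields": {"comment": "ok"}},
        )
        assert resp.status == 200
        assert len(resp.body["updated"]) == 4
        resp = api(
            "DELETE", "/electrophysiology/event/", params={"label": "stimulus"}
        )
        assert resp.body == {"deleted": 4}
        assert api("GET", "/electrophysiology/event/").body["total"] == 0


class TestStatusCodes:
    def test_missing_object_is_404_with_json_message(self, api):
        resp = api("GET", "/electrophysiology/spiketrain/ZZZZZZZZZZ/")
        assert resp.status == 404
        assert "message" in resp.body

    def test_unknown_namespace_and_type_are_404(self, api):
        assert api("GET", "/physiology/block/").status == 404
        assert api("GET", "/electrophysiology/tetrode/").status == 404
        assert api("GET", "/metadata/spiketrain/").status == 404

    def test_foreign_private_object_is_403(self, api):
        resp = api(
            "GET",
            f"/electrophysiology/segment/{api.ids['seg1']}/",
            actor="bob",
        )
        assert resp.status == 403
        assert "message" in resp.body

    def test_malformed_body_is_400(self, api):
        resp = api(
            "POST",
            "/electrophysiology/event/",
            body={"label": "x", "time": {"value": "soon"}, "segment": api.ids["seg1"]},
        )
        assert resp.status == 400
        assert "message" in resp.body

    def test_validation_failure_is_400(self, api):
        resp = api("POST", "/electrophysiology/analogsignal/", body={"name": "x"})
        assert resp.status == 400
        assert "violations" in resp.body

    def test_update_after_delete_is_410(self, api):
        ev = api(
            "POST",
            "/electrophysiology/event/",
            body={
                "label": "tmp",
                "time": {"value": 1, "units": "ms"},
                "segment": api.ids["seg1"],
            },
        ).body
        api("DELETE", ev["location"])
        assert api("GET", ev["location"]).status == 404
        assert api("POST", ev["location"], body={"label": "x"}).status == 410

    def test_stale_if_match_is_412(self, api):
        path = f"/electrophysiology/segment/{api.ids['seg1']}/"
        api("POST", path, body={"comment": "first"})
        resp = api(
            "POST", path, body={"comment": "second"}, headers={"If-Match": "stale"}
        )
        assert resp.status == 412


class TestConditionalGet:
    def test_etag_cycle_200_304_200(self, api):
        path = f"/electrophysiology/segment/{api.ids['seg2']}/"
        first = api("GET", path)
        etag = first.headers["ETag"]
        cached = api("GET", path, headers={"If-None-Match": etag})
        assert cached.status == 304
        assert cached.body is None
        api("POST", path, body={"comment": "touched"})
        after = api("GET", path, headers={"If-None-Match": etag})
        assert after.status == 200
        assert after.headers["ETag"] != etag

    def test_if_modified_since_honored(self, api):
        path = f"/electrophysiology/segment/{api.ids['seg2']}/"
        first = api("GET", path)
        resp = api(
            "GET", path, headers={"If-Modified-Since": first.headers["Last-Modified"]}
        )
        assert resp.status == 304

    def test_no_conditional_headers_gets_full_body(self, api):
        path = f"/electrophysiology/segment/{api.ids['seg2']}/"
        assert api("GET", path).status == 200


class TestSerialization:
    def test_quantities_and_arrays_in_documents(self, api):
        sig = api("GET", f"/electrophysiology/analogsignal/{api.ids['sig.t1.c1']}/")
        fields = sig.body["fields"]
        assert fields["t_start"] == {"value": 0.0, "units": "ms"}
        assert fields["signal"]["units"] == "uV"
        assert fields["signal"]["length"] == 1000
        assert fields["signal"]["url"].startswith("/datafiles/")

    def test_round_trip_reproduces_fields(self, experiment_graph):
        for obj in experiment_graph.objects:
            doc = fields_to_document(obj.fields)
            assert deserialize(obj.kind, doc) == obj.fields, obj.key

    def test_malformed_document_names_offending_keys(self):
        from ephyshub.errors import BadRequest

        with pytest.raises(BadRequest) as err:
            deserialize("analogsignal", {"signal": {"nonsense": 1}})
        assert err.value.details["fields"] == ["signal"]


def _payload_array(payload):
    with h5py.File(io.BytesIO(payload), "r") as f:
        return f["data"][()]


class TestDatafiles:
    def test_full_download_round_trips(self, api, loaded_store):
        store, ids = loaded_store
        ref = store.get_object(ids["sig.t1.c1"], "alice").fields["signal"]
        resp = api("GET", f"/datafiles/{ref.file_id}/")
        assert resp.status == 200
        assert resp.headers["Content-Type"] == "application/x-hdf5"
        assert np.array_equal(
            _payload_array(resp.body), store.load_array(ref.file_id)
        )

    def test_bounded_download_returns_the_slice(self, api, loaded_store):
        store, ids = loaded_store
        ref = store.get_object(ids["sig.t1.c1"], "alice").fields["signal"]
        resp = api(
            "GET",
            f"/datafiles/{ref.file_id}/",
            params={"start_index": "50", "end_index": "149"},
        )
        got = _payload_array(resp.body)
        assert got.shape == (100,)
        assert np.array_equal(got, store.load_array(ref.file_id)[50:150])

    def test_out_of_range_bounds_are_400_unknown_file_404(self, api, loaded_store):
        store, ids = loaded_store
        ref = store.get_object(ids["sig.t1.c1"], "alice").fields["signal"]
        resp = api(
            "GET",
            f"/datafiles/{ref.file_id}/",
            params={"start_index": "0", "end_index": "1000"},
        )
        assert resp.status == 400
        assert api("GET", "/datafiles/ZZZZZZZZZZ/").status == 404


class TestPartialDataRequests:
    def test_signal_document_embeds_index_bounds(self, api):
        resp = api(
            "GET",
            f"/electrophysiology/analogsignal/{api.ids['sig.t1.c1']}/",
            params={"start_time": "50", "duration": "100"},
        )
        doc = resp.body["fields"]["signal"]
        assert doc["url"].endswith("start_index=50&end_index=149")
        assert doc["length"] == 100

    def test_window_outside_signal_is_400(self, api):
        resp = api(
            "GET",
            f"/electrophysiology/analogsignal/{api.ids['sig.t1.c1']}/",
            params={"start_time": "5000"},
        )
        assert resp.status == 400

    def test_spiketrain_window_filters_times(self, api, loaded_store):
        store, ids = loaded_store
        ref = store.get_object(ids["st.t1.u3"], "alice").fields["times"]
        times_ms = store.load_array(ref.file_id)
        resp = api(
            "GET",
            f"/electrophysiology/spiketrain/{ids['st.t1.u3']}/",
            params={"start_time": "100", "end_time": "600"},
        )
        doc = resp.body["fields"]["times"]
        expected = [t for t in times_ms if 100 <= t < 600]
        assert doc["length"] == len(expected)


class TestVersionedReads:
    def test_at_time_parameter_travels_back(self, api):
        path = f"/electrophysiology/segment/{api.ids['seg3']}/"
        before = api("GET", path).body
        api("POST", path, body={"name": "renamed trial"})
        old = api("GET", path, params={"at_time": before["valid_from"]})
        assert old.status == 200
        assert old.body["fields"]["name"] == "trial 3"
        assert api("GET", path).body["fields"]["name"] == "renamed trial"
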