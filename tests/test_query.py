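"""Field-lookup queries checked against a brute-force in-memory oracle."""

import random

import pytest

from ephyshub import evaluate_query, parse_query_params
from ephyshub.errors import BadRequest
from ephyshub.permissions import effective_access
from ephyshub.query import QuerySpec, match_filter
from ephyshub.store import ObjectStore


class TestParsing:
    def test_lookup_key_parsed(self):
        spec = parse_query_params({"name__icontains": "luminance"}, "property")
        (flt,) = spec.filters
        assert (flt.relation, flt.fieldname, flt.lookup, flt.value) == (
            None,
            "name",
            "icontains",
            "luminance",
        )

    def test_bare_field_means_exact_and_reserved_keys_routed(self):
        spec = parse_query_params({"label": "stimulus", "owner": "demo"}, "event")
        (flt,) = spec.filters
        assert (flt.fieldname, flt.lookup, flt.value) == ("label", "exact", "stimulus")
        assert spec.owner == "demo"

    def test_relationship_path_parsed(self):
        spec = parse_query_params({"property__name__icontains": "lum"}, "value")
        (flt,) = spec.filters
        assert (flt.relation, flt.fieldname, flt.lookup) == (
            "property",
            "name",
            "icontains",
        )

    @pytest.mark.parametrize(
        "params,kind",
        [
            ({"name__regexx": "x"}, "block"),  # unknown lookup
            ({"colour": "red"}, "block"),  # unknown field
            ({"segment__block__name": "x"}, "analogsignal"),  # too deep
            ({"sibling__name": "x"}, "segment"),  # undeclared relation
            ({"offset": "-1"}, "block"),
        ],
    )
    def test_malformed_parameters_rejected(self, params, kind):
        with pytest.raises(BadRequest):
            parse_query_params(params, kind)

    def test_metadata_comma_list_and_pagination(self):
        spec = parse_query_params(
            {"metadata": "A2A2A2A2A2,B3B3B3B3B3", "offset": "2", "max_results": "5"},
            "analogsignal",
        )
        assert spec.metadata_values == ["A2A2A2A2A2", "B3B3B3B3B3"]
        assert (spec.offset, spec.max_results) == (2, 5)

    def test_max_results_hard_cap(self):
        spec = parse_query_params({"max_results": "99999"}, "block")
        assert spec.max_results == 1000


class TestEvaluation:
    def test_icontains_is_case_insensitive_substring(self, loaded_store):
        store, _ = loaded_store
        for name in ("luminance1", "contrast", "Luminance"):
            store.create_object("block", {"name": name}, "alice")
        spec = parse_query_params({"name__icontains": "luminance"}, "block")
        records, total = evaluate_query(spec, "alice", store)
        assert total == 2
        assert {r.fields["name"] for r in records} == {"luminance1", "Luminance"}

    def test_values_selected_through_parent_property_name(self, loaded_store):
        store, ids = loaded_store
        spec = parse_query_params({"property__name__icontains": "orient"}, "value")
        records, _ = evaluate_query(spec, "alice", store)
        expected = {
            ids[f"stim{t}.orientation.value"] for t in range(1, 5)
        }
        assert {r.id for r in records} == expected

    def test_metadata_conjunction_selects_doubly_annotated_only(self, loaded_store):
        store, ids = loaded_store
        v1 = ids["stim1.orientation.value"]
        v2 = ids["stim1.size.value"]
        spec = QuerySpec(kind="segment", metadata_values=[v1, v2])
        records, _ = evaluate_query(spec, "alice", store)
        assert [r.id for r in records] == [ids["seg1"]]
        # a single shared value alone is not enough for the conjunction
        spec2 = QuerySpec(kind="segment", metadata_values=[v1, ids["stim2.size.value"]])
        assert evaluate_query(spec2, "alice", store)[1] == 0

    def test_pagination_slices_stable_order(self, store):
        created = [
            store.create_object("block", {"name": f"b{i}"}, "alice") for i in range(5)
        ]
        spec = QuerySpec(kind="block", offset=2, max_results=2)
        records, total = evaluate_query(spec, "alice", store)
        assert total == 5
        assert [r.id for r in records] == [created[2].id, created[3].id]

    def test_pages_concatenate_to_full_result(self, loaded_store):
        store, _ = loaded_store
        full, total = evaluate_query(
            QuerySpec(kind="analogsignal", max_results=1000), "alice", store
        )
        paged = []
        for offset in range(0, total, 7):
            page, _ = evaluate_query(
                QuerySpec(kind="analogsignal", offset=offset, max_results=7),
                "alice",
                store,
            )
            paged.extend(r.id for r in page)
        assert paged == [r.id for r in full]


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence on randomized stores.

LOOKUP_POOL = [
    ("name", "exact", "obj3"),
    ("name", "iexact", "OBJ3"),
    ("name", "contains", "j1"),
    ("name", "icontains", "J1"),
    ("name", "startswith", "obj1"),
    ("name", "in", "obj1,obj4,nope"),
    ("name", "gt", "obj5"),
    ("name", "lte", "obj3"),
    ("comment", "isnull", "true"),
    ("index", "gte", "3"),
    ("index", "lt", "5"),
]


def _build_random_store(seed):
    rng = random.Random(seed)
    store = ObjectStore(rng=random.Random(seed + 1))
    for u in ("alice", "bob"):
        store.identity.register(u)
    groups = []
    for g in range(3):
        owner = rng.choice(["alice", "bob"])
        rec = store.create_object(
            "recordingchannelgroup", {"name": f"group{g}"}, owner
        )
        if rng.random() < 0.5:
            store.set_acl(rec.id, {"safety_level": "public"}, owner)
        groups.append(rec)
    for i in range(rng.randint(30, 80)):
        owner = rng.choice(["alice", "bob"])
        fields = {"name": f"obj{rng.randint(0, 9)}"}
        if rng.random() < 0.5:
            fields["comment"] = f"note {i}"
        if rng.random() < 0.7:
            fields["index"] = rng.randint(0, 9)
        if rng.random() < 0.8:
            fields["recordingchannelgroup"] = rng.choice(groups).id
        rec = store.create_object("recordingchannel", fields, owner)
        roll = rng.random()
        if roll < 0.25:
            store.set_acl(rec.id, {"safety_level": "public"}, owner)
        elif roll < 0.45:
            other = "bob" if owner == "alice" else "alice"
            store.set_acl(
                rec.id, {"shared_with": {other: rng.choice(["read", "read-write"])}},
                owner,
            )
        if rng.random() < 0.1:
            store.delete_object(rec.id, owner)
    return store


def _brute_force(store, kind, actor, filters):
    """Oracle: scan every live record, re-deriving visibility and matches."""
    out = []
    for oid in store.ids_of_kind(kind):
        rec = store.version_at(oid, None)
        if rec is None:
            continue
        if effective_access(store.acl_of(oid), actor) == "none":
            continue
        ok = True
        for relation, fieldname, lookup, value in filters:
            if relation is None:
                stored = rec.fields.get(fieldname)
            else:
                pid = rec.fields.get(relation)
                parent = store.version_at(pid, None) if pid else None
                if parent is None:
                    ok = pid is None and lookup == "isnull" and value == "true"
                    if not ok:
                        break
                    continue
                stored = parent.fields.get(fieldname)
            if not match_filter(stored, lookup, value):
                ok = False
                break
        if ok:
            out.append(rec.id)
    order = {
        oid: (store.version_at(oid, None).valid_from, oid)
        for oid in out
    }
    return sorted(out, key=order.__getitem__)


@pytest.mark.parametrize("seed", range(6))
def test_every_lookup_matches_brute_force(seed):
    store = _build_random_store(seed)
    for actor in ("alice", "bob", None):
        for fieldname, lookup, value in LOOKUP_POOL:
            params = {f"{fieldname}__{lookup}": value}
            spec = parse_query_params(params, "recordingchannel")
            spec.max_results = 1000
            got = [r.id for r in evaluate_query(spec, actor, store)[0]]
            expected = _brute_force(
                store, "recordingchannel", actor, [(None, fieldname, lookup, value)]
            )
            assert got == expected, (actor, fieldname, lookup)


@pytest.mark.parametrize("seed", range(6))
def test_relationship_paths_and_and_semantics_match_brute_force(seed):
    store = _build_random_store(seed + 100)
    params = {
        "recordingchannelgroup__name__icontains": "group",
        "name__startswith": "obj",
    }
    spec = parse_query_params(params, "recordingchannel")
    spec.max_results = 1000
    got = [r.id for r in evaluate_query(spec, "alice", store)[0]]
    filters = [
        ("recordingchannelgroup", "name", "icontains", "group"),
        (None, "name", "startswith", "obj"),
    ]
    assert got == _brute_force(store, "recordingchannel", "alice", filters)

    # AND semantics: the combined result is the intersection of singles
    singles = [
        set(
            r.id
            for r in evaluate_query(
                parse_query_params({k: v}, "recordingchannel"), "alice", store
            )[0]
        )
        for k, v in params.items()
    ]
    assert set(got) == singles[0] & singles[1]


@pytest.mark.parametrize("seed", range(4))
def test_visibility_equals_individual_access(seed):
    """No record is listed for an actor who could not fetch it directly."""
    store = _build_random_store(seed + 200)
    for actor in ("alice", "bob", None):
        spec = QuerySpec(kind="recordingchannel", max_results=1000)
        listed = {r.id for r in evaluate_query(spec, actor, store)[0]}
        for oid in store.ids_of_kind("recordingchannel"):
            if store.version_at(oid, None) is None:
                continue
            visible = effective_access(store.acl_of(oid), actor) != "none"
            assert (oid in listed) == visible
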