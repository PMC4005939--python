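from datetime import datetime, timedelta, timezone

import pytest

from ephyshub import (
    ExperimentSpec,
    Identity,
    InProcessTransport,
    ObjectStore,
    RestService,
    Session,
    generate_experiment,
    load_into_store,
)

BASE_TIME = datetime(2014, 4, 23, 12, 0, 0, tzinfo=timezone.utc)


def at(seconds: float) -> datetime:
    return BASE_TIME + timedelta(seconds=seconds)


@pytest.fixture
def identity():
    ident = Identity()
    for user in ("alice", "bob", "carol"):
        ident.register(user, f"{user}-token")
    return ident


@pytest.fixture
def store(tmp_path, identity):
    import random

    return ObjectStore(root=tmp_path, rng=random.Random(7), identity=identity)


@pytest.fixture
def service(store, identity):
    return RestService(store=store, identity=identity)


@pytest.fixture
def session(service):
    return Session(InProcessTransport(service, "alice-token"))


@pytest.fixture(scope="session")
def experiment_graph():
    return generate_experiment(ExperimentSpec(seed=42))


@pytest.fixture
def loaded_store(store, experiment_graph):
    key_to_id = load_into_store(experiment_graph, store, owner="alice")
    return store, key_to_id
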