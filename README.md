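# ephyshub

A versioned object store and REST-style API for electrophysiology data and
its experimental metadata, with a native Python client.

Electrophysiology labs accumulate recorded signals (local field potentials,
spike trains) alongside the experimental context that makes them analyzable
— stimulus parameters, preparation details, hardware settings.  `ephyshub`
keeps both in one store under a single interface: recorded data follows the
Neo-style object model (a **block** of experimental trials, each trial a
**segment** holding **analogsignals**, **spiketrains** of sorted **units**
and stimulus **events**, with **recordingchannels** grouped per electrode
array), and metadata follows the odML-style model of nested **sections**
holding **properties** with **values**.  Any data object can be *annotated*
by linking it to metadata values, which makes data selectable by
experimental condition ("all trials where orientation = 60°").

The store is fully versioned: every write produces a new object version
with a fresh e-Tag, validity intervals partition time, and any historical
state is retrievable with an `at_time` timestamp.  Deletes are tombstones —
invisible to live reads, preserved in history.  Numeric arrays live in HDF5
files (one dataset at the file root per array) and support *partial data
requests*: a half-open time window `[start, end)` is resolved against the
object's `t_start` and `sampling_rate` into inclusive first/last array
indices, so only the needed samples are transferred.

## Interface

* **REST dispatcher** (`ephyshub.rest.RestService.route_request`) with the
  URL grammar `/namespace/object_type/[id/[acl/]]` over the namespaces
  `electrophysiology`, `metadata` and `datafiles`; GET lists/fetches, POST
  creates/updates/annotates, DELETE removes (soft);
  `DELETE .../acl/` answers 405.  Query parameters use Django-style field
  lookups (`name__icontains=luminance`,
  `property__name__icontains=luminance`, `metadata=ID1,ID2`, `owner`,
  `at_time`, `offset`, `max_results`).  Conditional GET via
  `If-None-Match` / `If-Modified-Since` returns 304 when unchanged.
* **Access control**: every object is private to its owner at creation;
  the owner can grant per-user read or read-write shares or make the
  object public, per object or recursively over a container.
* **Client library** (`ephyshub.Session`) over either real HTTP
  (`HttpTransport`, stdlib only) or an in-process transport; arrays are
  fetched lazily, optionally server-sliced to a window; updates use
  optimistic concurrency (`If-Match`, conflict on stale e-Tag); repeat
  reads revalidate with e-Tags.
* **Synthetic sessions** (`ephyshub.fixtures`): a seeded generator that
  emulates a receptive-field mapping experiment — per-trial stimulus
  metadata (orientation in multiples of 30°, size), 12-channel LFP
  (smoothed Gaussian noise, 50 µV SD, 1 kHz) and Poisson spike trains of
  3 sorted units — used throughout the tests and loadable through the CLI.

## Worked example

```python
from ephyshub import (ExperimentSpec, Identity, InProcessTransport, ObjectStore,
                      RestService, Session, SliceWindow, generate_experiment)
from ephyshub.fixtures import push_experiment

identity = Identity()
token = identity.register("demo")
service = RestService(store=ObjectStore(identity=identity), identity=identity)
session = Session(InProcessTransport(service, token))

graph = generate_experiment(ExperimentSpec(seed=42))   # 4 trials, 12 channels, 3 units
pushed = push_experiment(graph, session)
print(f"pushed {len(pushed)} objects")

signals = session.select("analogsignal", {"name__icontains": "RC1 "})
print(f"{len(signals)} signals on channel RC1; first id {signals[0].id}")

window = SliceWindow(0.05, 0.15)          # 50 ms .. 150 ms
samples = session.fetch_array(signals[0], window=window)
print(f"windowed fetch: {samples.size} samples, first = {samples[0]:.3f} uV")

trial1 = session.get("segment", pushed["seg1"].id)
hits = session.select("segment", {"metadata": ",".join(trial1.fields["metadata"])})
print(f"segments annotated with trial 1's stimulus values: "
      f"{[h.fields['name'] for h in hits]}")
```

prints (object ids vary with the store's id stream):

```
pushed 106 objects
4 signals on channel RC1; first id DANNSPWR4X
windowed fetch: 100 samples, first = 1.412 uV
segments annotated with trial 1's stimulus values: ['trial 1']
```

The 106 objects are the full session graph (1 block, 4 segments, 48
signals, 12 spike trains, plus channels, units, events and the stimulus
metadata tree).  The windowed fetch returns exactly the 100 samples of a
1 kHz signal whose timestamps fall in [50 ms, 150 ms); the final query
selects precisely the one trial annotated with those stimulus values.

A development server is also available from the shell:

```bash
ephyshub serve --port 8000 --user demo:demo
ephyshub load-fixtures --base-url http://127.0.0.1:8000 --token demo --seed 42
ephyshub query segment name__icontains=trial --base-url http://127.0.0.1:8000 --token demo
```

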