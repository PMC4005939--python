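# Methods

This note documents the data model, the protocol semantics, the numerical
conventions and the synthetic-data generator behind `ephyshub`, including
the choices made where the design was genuinely open.

## Object model

Recorded data uses the Neo-style hierarchy (block → segment →
analogsignal / spiketrain / event, with recordingchannelgroup →
recordingchannel and unit as signal sources); metadata uses the odML-style
hierarchy (section → property → value, sections nest freely as long as the
parent links form a forest).  The attribute schema per kind is a frozen
declarative table (`ephyshub.model.SCHEMAS`): required and optional
attributes, their types, unit dimension for quantities and arrays, and the
allowed parent kinds.  The table is our reconstruction of what a minimal
working subset of the Neo/odML models needs; it deliberately omits Neo
API conveniences (lazy proxies, I/O) and odML terminology templates.

Notable schema decisions:

* `analogsignal`, `spiketrain` and `event` require a `segment` parent;
  containers (`segment`, `recordingchannelgroup`, `section`) may be
  created before their own parents are linked.
* Spike times must arrive sorted and inside `[t_start, t_stop)`; unsorted
  input is rejected, never silently sorted (explicit over implicit).
* Metadata values carry a bare number-or-text `data` attribute; units and
  uncertainty on values are not modeled.  Stimulus quantities in practice
  carry their unit in the property name or convention (e.g. orientation in
  degrees).
* Every kind accepts an optional free-text `comment`.

### Units

Quantities are `(value, units)` pairs over a closed table — time: s, ms,
µs (`us`); frequency: Hz, kHz; voltage: V, mV, µV (`uV`).  Conversion
within a dimension is an exact power-of-ten rescale; canonical base units
are s, Hz, V.  Unknown symbols and cross-dimension conversions are errors.
The round trip canonicalize → convert-back is exact to ≤1e-12 relative
error (it is a single multiply and divide by exact binary-representable
powers of ten times the value).

## Versioned store

Each object is an append-only list of immutable versions carrying
`[valid_from, valid_to)` validity intervals; the intervals are contiguous
by construction (each update closes the previous interval at the new
version's `valid_from`) and exactly one interval is open iff the object is
live.  Timestamps are UTC at microsecond resolution; when the caller does
not supply one, a monotonic clock guarantees strictly increasing stamps
even within one microsecond of wall time.  `at_time` reads select the
version whose interval contains the instant; times before creation are
not-found.

* **Deletion** is a tombstone version holding the last field state:
  live reads and queries no longer see the object, `at_time` reads before
  the deletion still do, and updates after deletion answer 410 Gone.
* **e-Tags** are a SHA-1 prefix of `(id, valid_from)`; since `valid_from`
  strictly increases per object, tags are pairwise distinct across a
  version history.  `Last-Modified` is the current version's
  `valid_from`.
* **Identifiers** are 10-character tokens over the RFC 4648 base-32
  alphabet (A–Z, 2–7), drawn from the store's seeded RNG with retry on
  collision (the space holds 32^10 ≈ 1.1e15 tokens).
* **Annotation** links metadata values to a data object with set
  semantics, stored as a sorted id list in the `metadata` field.  Adding a
  link is a content change and creates a new version (and e-Tag); a
  no-op annotation (all links already present) creates none.
* **Backend**: an in-memory version log plus one HDF5 file per array
  under the store directory.  The store interface (`create/update/delete/
  get/annotate/store_array/load_array`) hides the backend entirely, so a
  relational implementation could be swapped in without touching the
  layers above.  Multi-process concurrency is out of scope; the intended
  deployment of this implementation is a single-process server.

ACLs are administrative state beside the version log: changing permissions
does not create an object version or change the e-Tag, since the object's
content is unchanged and caches keyed on content would otherwise be
invalidated spuriously.

## Queries

Filters use the Django field-lookup syntax with a closed lookup set
(`exact`, `iexact`, `contains`, `icontains`, `gt`, `gte`, `lt`, `lte`,
`in`, `startswith`, `isnull`) and relationship paths of depth ≤ 2 through
declared parent links (`property__name__icontains=...`).  Multiple filters
AND together; `metadata=ID1,ID2` demands *all* listed annotation links.
Comparisons coerce the URL string to the stored value's type; quantity
attributes compare on their canonical base-unit magnitude.  Ordering
lookups on text compare lexicographically.

Result order is the stable key `(valid_from of the selected version, id)`;
pagination is `offset`/`max_results` with default 100 and hard cap 1000.
`at_time` in a query performs version selection *before* filtering, so a
historical query sees historical attribute values.  Visibility is exactly
per-object read access — a query never returns a record the actor could
not fetch individually.

## Partial data requests

Windows are half-open `[start, end)`.  This makes window composition
exact: windows tiling the time axis produce disjoint, gap-free index
ranges (verified by a property test).  For a signal with start time `t0`
and rate `r`, sample `i` has timestamp `t0 + i/r`; the first index is the
tolerant ceiling of `(start − t0)·r` and the last index is the largest `i`
with `t_i < end`.  Boundary comparisons use a relative tolerance of 1e-9
on canonical seconds so that unit conversion round-off (e.g. ms → s)
cannot shift a boundary sample into or out of the window.  Spike trains
are filtered by membership; the in-window subset of a sorted train is
contiguous, so it is also expressible as inclusive index bounds.

Request parameters are `start_time`, `end_time`, `duration` (at most one
of the latter two); numeric values are interpreted in the units of the
object's `t_start` attribute.  Missing start defaults to the signal start;
missing end to the signal end; `duration` without `start_time` anchors at
the signal start.  Sliced datafiles contain raw numbers only — units,
start time and rate must be read from the parent object.

## REST contract decisions

Where the protocol leaves response shapes open, this implementation fixes
them as follows (they are part of this package's contract, not of any
external standard): list responses use the envelope
`{objects, total, offset, max_results}`; creation answers 201 with the
created document, updates 200; bulk updates POST
`{ids | filters, fields}` to the type URL; the ACL document is
`{safety_level: private|public, shared_with: {user: read|read-write}}`
with an optional `recursive` flag on POST that applies the same ACL to all
contained objects owned by the caller.  Authentication is a bearer-token
stub mapping tokens to user ids — a deliberate seam where a real identity
backend would plug in.  Client saves send `If-Match` with the locally
known e-Tag; a stale tag answers 412, surfacing concurrent edits instead
of losing them.  Groups in ACLs are not modeled; one share per user
covers the use cases exercised here.

## Synthetic sessions

The generator emulates a visual-cortex receptive-field mapping experiment:
per trial a unique stimulus configuration, LFPs on a 12-channel array and
spike trains of 3 sorted units.  Defaults: 4 trials of 1 s at 1 kHz
(1000 samples), orientation drawn from multiples of 30° and size from
{0.5, 1.0, 2.0} degrees of visual angle, per-unit Poisson rates of 5, 10
and 20 Hz (plausible cortical firing rates spanning sparse to brisk), LFP
traces as Gaussian white noise smoothed with a σ = 5-sample Gaussian
kernel and scaled to a 50 µV standard deviation — typical LFP amplitude
scale.  All randomness flows from one `numpy` generator seeded by the
spec, so equal specs give bit-identical graphs.

The generator emulates structure, not physiology: signals have no
oscillatory spectrum or stimulus-locked response, spike trains are
homogeneous (no refractoriness or tuning), and metadata is limited to two
stimulus properties.  Tests passing on these fixtures therefore establish
the storage, protocol and query semantics — not any claim about analysis
of real recordings.

## Problem sizes in the verification suite

The oracle-based checks run at sizes chosen to exercise every code path
while keeping the suite quick to iterate on: 1000 random
(start, rate, length, window) tuples for the slicing oracle, 500 random
create/update/delete histories for the versioning oracle, randomized
stores of 100–200 live objects (≈ 500 with metadata and history) for the
query oracle, and the full seed-42 session (106 objects, 60 arrays) for
the end-to-end round trip.  All of these are computed fresh at run time by
`scripts/acceptance.py`; nothing in the reported numbers is stored.

## Known limitations

* Single-process, in-memory metadata: the version log is not persisted
  across server restarts (arrays on disk are).
* No OR in the filter dialect, no filters over array contents, no
  full-text search.
* The WSGI development server is single-threaded; it is meant for local
  use and tests, not deployment.
* `If-Modified-Since` has whole-second resolution (HTTP date format);
  e-Tag revalidation is the precise mechanism.
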