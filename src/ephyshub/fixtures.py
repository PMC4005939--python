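"""Seedable synthetic experiment generator.

Emulates a receptive-field mapping session in visual cortex: one dataset
(block) of trials, each trial with its own stimulus configuration
(orientation in multiples of 30 degrees, size in degrees of visual angle),
local field potentials recorded on a 12-channel array (RC1..RC12) and spike
trains of three sorted units (U1..U3).  Signals are smoothed Gaussian noise
with an LFP-like amplitude (~50 uV standard deviation); spike trains are
homogeneous Poisson processes with a fixed rate per unit.  Each trial's
stimulus parameters live in a metadata section whose values annotate that
trial's segment, so trials can be selected by stimulus condition.

Generation is a pure function of the spec: equal specs (including the seed)
produce bit-identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import model
from .client import RemoteObject, Session
from .errors import BadRequest
from .model import ArrayValue, Quantity
from .store import ObjectStore

#: mean firing rate per sorted unit, Hz (cycled when n_units > 3)
UNIT_RATES_HZ = (5.0, 10.0, 20.0)
#: LFP amplitude: standard deviation of the smoothed noise, uV
LFP_STD_UV = 50.0
#: Gaussian smoothing kernel width, samples
SMOOTH_SIGMA = 5.0

ORIENTATIONS_DEG = tuple(range(0, 360, 30))
SIZES_DEG = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class ExperimentSpec:
    n_trials: int = 4
    n_channels: int = 12
    n_units: int = 3
    samples_per_trial: int = 1000
    sampling_rate: Quantity = Quantity(1.0, "kHz")
    seed: int = 42

    def __post_init__(self):
        for name in ("n_trials", "n_channels", "n_units", "samples_per_trial"):
            if getattr(self, name) < 1:
                raise BadRequest(f"{name} must be >= 1")

    @property
    def trial_duration_s(self) -> float:
        rate = model.canonicalize_quantity(self.sampling_rate, "frequency").value
        return self.samples_per_trial / rate


@dataclass(frozen=True)
class LocalObject:
    """One object of the generated graph; parent links are local keys."""

    key: str
    kind: str
    fields: dict


@dataclass
class ExperimentGraph:
    spec: ExperimentSpec
    objects: list[LocalObject] = dc_field(default_factory=list)
    #: (segment key, metadata value key) annotation links
    annotations: list[tuple[str, str]] = dc_field(default_factory=list)

    def by_key(self, key: str) -> LocalObject:
        return next(o for o in self.objects if o.key == key)

    def of_kind(self, kind: str) -> list[LocalObject]:
        return [o for o in self.objects if o.kind == kind]


def _lfp_trace(rng: np.random.Generator, n: int) -> np.ndarray:
    white = rng.standard_normal(n)
    half = int(4 * SMOOTH_SIGMA)
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / SMOOTH_SIGMA) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(white, kernel, mode="same")
    sd = smooth.std()
    return smooth * (LFP_STD_UV / sd) if sd > 0 else smooth


def _poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float):
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def generate_experiment(spec: ExperimentSpec) -> ExperimentGraph:
    """Build the full object graph for one synthetic session."""
    rng = np.random.default_rng(spec.seed)
    graph = ExperimentGraph(spec=spec)
    add = graph.objects.append

    add(LocalObject("block", "block", {"name": "receptive-field mapping session"}))
    add(
        LocalObject(
            "rcg",
            "recordingchannelgroup",
            {"name": "electrode array", "block": "block"},
        )
    )
    for c in range(spec.n_channels):
        add(
            LocalObject(
                f"rc{c + 1}",
                "recordingchannel",
                {"name": f"RC{c + 1}", "index": c + 1, "recordingchannelgroup": "rcg"},
            )
        )
    for u in range(spec.n_units):
        add(
            LocalObject(
                f"u{u + 1}", "unit", {"name": f"U{u + 1}", "recordingchannelgroup": "rcg"}
            )
        )
    add(
        LocalObject(
            "protocol", "section", {"name": "experiment protocol", "block": "block"}
        )
    )

    duration_s = spec.trial_duration_s
    for t in range(spec.n_trials):
        seg = f"seg{t + 1}"
        add(LocalObject(seg, "segment", {"name": f"trial {t + 1}", "block": "block"}))
        add(
            LocalObject(
                f"ev{t + 1}",
                "event",
                {
                    "label": "stimulus",
                    "time": Quantity(0.0, "ms"),
                    "segment": seg,
                },
            )
        )
        sec = f"stim{t + 1}"
        add(
            LocalObject(
                sec,
                "section",
                {"name": f"trial {t + 1} stimulus", "parent_section": "protocol"},
            )
        )
        orientation = int(rng.choice(ORIENTATIONS_DEG))
        size = float(rng.choice(SIZES_DEG))
        for prop_name, value in (("orientation", orientation), ("size", size)):
            pkey = f"{sec}.{prop_name}"
            vkey = f"{pkey}.value"
            add(LocalObject(pkey, "property", {"name": prop_name, "section": sec}))
            add(LocalObject(vkey, "value", {"data": value, "property": pkey}))
            graph.annotations.append((seg, vkey))

        for c in range(spec.n_channels):
            add(
                LocalObject(
                    f"sig.t{t + 1}.c{c + 1}",
                    "analogsignal",
                    {
                        "name": f"trial {t + 1} RC{c + 1} LFP",
                        "t_start": Quantity(0.0, "ms"),
                        "sampling_rate": spec.sampling_rate,
                        "signal": ArrayValue(
                            _lfp_trace(rng, spec.samples_per_trial), "uV"
                        ),
                        "segment": seg,
                        "recordingchannel": f"rc{c + 1}",
                    },
                )
            )
        for u in range(spec.n_units):
            rate = UNIT_RATES_HZ[u % len(UNIT_RATES_HZ)]
            times_ms = _poisson_train(rng, rate, duration_s) * 1e3
            add(
                LocalObject(
                    f"st.t{t + 1}.u{u + 1}",
                    "spiketrain",
                    {
                        "name": f"trial {t + 1} U{u + 1} spikes",
                        "t_start": Quantity(0.0, "ms"),
                        "t_stop": Quantity(duration_s * 1e3, "ms"),
                        "times": ArrayValue(times_ms, "ms"),
                        "segment": seg,
                        "unit": f"u{u + 1}",
                    },
                )
            )
    return graph


def _resolve_refs(obj: LocalObject, key_to_id: dict) -> dict:
    schema = model.schema_for(obj.kind)
    fields = dict(obj.fields)
    for parent in schema.parents:
        ref = fields.get(parent.name)
        if ref is not None:
            fields[parent.name] = key_to_id[ref]
    return fields


def load_into_store(
    graph: ExperimentGraph, store: ObjectStore, owner: str
) -> dict[str, str]:
    """Materialize a generated graph directly in a store.

    Returns the mapping of local graph keys to assigned object ids.
    """
    key_to_id: dict[str, str] = {}
    for obj in graph.objects:
        record = store.create_object(obj.kind, _resolve_refs(obj, key_to_id), owner)
        key_to_id[obj.key] = record.id
    for seg_key, val_key in graph.annotations:
        store.annotate(key_to_id[seg_key], [key_to_id[val_key]], owner)
    return key_to_id


def push_experiment(graph: ExperimentGraph, session: Session) -> dict[str, RemoteObject]:
    """Upload a generated graph through the client library."""
    key_to_obj: dict[str, RemoteObject] = {}
    key_to_id: dict[str, str] = {}
    for obj in graph.objects:
        remote = session.save(
            RemoteObject(kind=obj.kind, fields=_resolve_refs(obj, key_to_id))
        )
        key_to_obj[obj.key] = remote
        key_to_id[obj.key] = remote.id
    for seg_key, val_key in graph.annotations:
        key_to_obj[seg_key] = session.annotate(
            key_to_obj[seg_key], [key_to_id[val_key]]
        )
    return key_to_obj
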