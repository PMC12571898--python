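"""Session container: aligned behavioural and neural data, HDF5/JSON I/O.

A session holds, per trial, the click train, the behavioural choice, the
movement-onset (fixation-exit) time relative to stimulus onset and the
trial start time within the session, and, per neuron, spike times per trial
relative to stimulus onset. Synthetic sessions additionally carry a
ground-truth block (latent paths and true commitment steps).

The on-disk container is HDF5 with a schema-version attribute; ragged
arrays are stored flat with offset vectors. A JSON mirror exists for small
plain-text fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np

from driftswitch.stimuli import ClickTrain

__all__ = [
    "SCHEMA_VERSION",
    "SessionValidationError",
    "TrialData",
    "Trial",
    "GroundTruth",
    "Session",
    "write_session",
    "read_session",
    "session_to_json",
    "session_from_json",
]

SCHEMA_VERSION = 1


class SessionValidationError(ValueError):
    """A mandatory field is missing or an invariant is violated."""


@dataclass(frozen=True)
class TrialData:
    """Behavioural record of one trial."""

    clicks: ClickTrain
    choice: str
    move_onset: float
    start_time: float

    def __post_init__(self) -> None:
        if self.choice not in ("L", "R"):
            raise SessionValidationError(f"choice must be 'L' or 'R', got {self.choice!r}")
        if self.move_onset <= 0:
            raise SessionValidationError("move_onset must be positive")


@dataclass(frozen=True)
class Trial:
    """One trial's stimulus, behaviour and spikes (view used by inference)."""

    clicks: ClickTrain
    choice: str
    move_onset: float
    start_time: float
    spike_times: list[np.ndarray]


@dataclass(frozen=True)
class GroundTruth:
    """Simulator provenance: latent paths and true commitment."""

    latents: list[np.ndarray]
    commit_step: np.ndarray
    commit_side: np.ndarray  # '' when uncommitted


@dataclass
class Session:
    """Aligned container of trials and per-neuron spike times.

    ``spike_times[n][i]`` is the spike-time array of neuron ``n`` on trial
    ``i`` (seconds from stimulus onset).
    """

    session_id: str
    trials: list[TrialData]
    neuron_ids: list[str]
    spike_times: list[list[np.ndarray]]
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_tr = len(self.trials)
        if len(self.neuron_ids) != len(self.spike_times):
            raise SessionValidationError("neuron_ids and spike_times lengths differ")
        starts = np.array([t.start_time for t in self.trials])
        if n_tr > 1 and np.any(np.diff(starts) <= 0):
            raise SessionValidationError("trial start times must be strictly increasing")
        for n, per_trial in enumerate(self.spike_times):
            if len(per_trial) != n_tr:
                raise SessionValidationError(
                    f"neuron {n} has {len(per_trial)} trials of spikes, expected {n_tr}"
                )
            for i, st in enumerate(per_trial):
                st = np.asarray(st, dtype=float)
                if st.size and np.any(np.diff(st) < 0):
                    raise SessionValidationError(
                        f"spike times of neuron {n}, trial {i} are not sorted"
                    )
                if st.size and st[0] < 0:
                    raise SessionValidationError(
                        f"negative spike time in neuron {n}, trial {i}"
                    )
        if self.ground_truth is not None:
            gt = self.ground_truth
            if len(gt.latents) != n_tr or len(gt.commit_step) != n_tr:
                raise SessionValidationError("ground truth does not match trial count")

    # -- accessors ----------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def trial(self, i: int) -> Trial:
        t = self.trials[i]
        return Trial(
            clicks=t.clicks,
            choice=t.choice,
            move_onset=t.move_onset,
            start_time=t.start_time,
            spike_times=[np.asarray(self.spike_times[n][i], dtype=float) for n in range(self.n_neurons)],
        )

    @property
    def choices(self) -> np.ndarray:
        return np.array([t.choice for t in self.trials])

    def subset(self, indices: Sequence[int]) -> "Session":
        """New session restricted to the given trials (order preserved by
        original trial order so start times stay increasing)."""
        idx = sorted(int(i) for i in indices)
        gt = None
        if self.ground_truth is not None:
            gt = GroundTruth(
                latents=[self.ground_truth.latents[i] for i in idx],
                commit_step=self.ground_truth.commit_step[idx],
                commit_side=self.ground_truth.commit_side[idx],
            )
        return Session(
            session_id=self.session_id,
            trials=[self.trials[i] for i in idx],
            neuron_ids=list(self.neuron_ids),
            spike_times=[[per[i] for i in idx] for per in self.spike_times],
            ground_truth=gt,
        )


# ---------------------------------------------------------------------------
# ragged helpers


def _flatten(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(len(arrays) + 1, dtype=np.int64)
    for i, a in enumerate(arrays):
        offsets[i + 1] = offsets[i] + len(a)
    flat = np.concatenate([np.asarray(a, dtype=float) for a in arrays]) if arrays else np.empty(0)
    return flat, offsets


def _unflatten(flat: np.ndarray, offsets: np.ndarray) -> list[np.ndarray]:
    return [flat[offsets[i] : offsets[i + 1]].copy() for i in range(len(offsets) - 1)]


# ---------------------------------------------------------------------------
# HDF5


def write_session(session: Session, path) -> None:
    """Write the session to an HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["session_id"] = session.session_id
        tg = f.create_group("trials")
        left, loff = _flatten([t.clicks.left_times for t in session.trials])
        right, roff = _flatten([t.clicks.right_times for t in session.trials])
        tg.create_dataset("left_times", data=left)
        tg.create_dataset("left_offsets", data=loff)
        tg.create_dataset("right_times", data=right)
        tg.create_dataset("right_offsets", data=roff)
        tg.create_dataset("duration", data=[t.clicks.duration for t in session.trials])
        tg.create_dataset(
            "choice", data=np.array([1 if t.choice == "R" else 0 for t in session.trials], dtype=np.int8)
        )
        tg.create_dataset("move_onset", data=[t.move_onset for t in session.trials])
        tg.create_dataset("start_time", data=[t.start_time for t in session.trials])
        ng = f.create_group("neurons")
        ng.create_dataset("ids", data=np.array(session.neuron_ids, dtype="S"))
        all_spikes = [st for per in session.spike_times for st in per]
        flat, off = _flatten(all_spikes)
        ng.create_dataset("spikes", data=flat)
        ng.create_dataset("spike_offsets", data=off)
        if session.ground_truth is not None:
            gg = f.create_group("ground_truth")
            lat, latoff = _flatten(session.ground_truth.latents)
            gg.create_dataset("latents", data=lat)
            gg.create_dataset("latent_offsets", data=latoff)
            gg.create_dataset("commit_step", data=session.ground_truth.commit_step.astype(np.int64))
            side = np.array(
                [{"": -1, "L": 0, "R": 1}[s] for s in session.ground_truth.commit_side],
                dtype=np.int8,
            )
            gg.create_dataset("commit_side", data=side)


def read_session(path) -> Session:
    """Read and validate a session container."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise SessionValidationError("missing schema_version attribute")
        if int(version) != SCHEMA_VERSION:
            raise SessionValidationError(
                f"unsupported schema version {version}; expected {SCHEMA_VERSION}"
            )
        session_id = str(f.attrs.get("session_id", ""))
        if "trials" not in f:
            raise SessionValidationError("missing mandatory group 'trials'")
        tg = f["trials"]
        for name in ("left_times", "right_times", "duration", "choice", "move_onset", "start_time"):
            if name not in tg:
                raise SessionValidationError(f"missing mandatory field 'trials/{name}'")
        left = _unflatten(tg["left_times"][...], tg["left_offsets"][...])
        right = _unflatten(tg["right_times"][...], tg["right_offsets"][...])
        durations = tg["duration"][...]
        choices = tg["choice"][...]
        moves = tg["move_onset"][...]
        starts = tg["start_time"][...]
        trials = [
            TrialData(
                clicks=ClickTrain(left_times=left[i], right_times=right[i], duration=float(durations[i])),
                choice="R" if choices[i] == 1 else "L",
                move_onset=float(moves[i]),
                start_time=float(starts[i]),
            )
            for i in range(len(durations))
        ]
        ng = f["neurons"]
        ids = [s.decode() for s in ng["ids"][...]]
        flat = _unflatten(ng["spikes"][...], ng["spike_offsets"][...])
        n_tr = len(trials)
        spikes = [flat[n * n_tr : (n + 1) * n_tr] for n in range(len(ids))]
        gt = None
        if "ground_truth" in f:
            gg = f["ground_truth"]
            gt = GroundTruth(
                latents=_unflatten(gg["latents"][...], gg["latent_offsets"][...]),
                commit_step=gg["commit_step"][...].astype(int),
                commit_side=np.array(
                    [{-1: "", 0: "L", 1: "R"}[int(v)] for v in gg["commit_side"][...]]
                ),
            )
    return Session(
        session_id=session_id,
        trials=trials,
        neuron_ids=ids,
        spike_times=spikes,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# JSON mirror (small plain-text fixtures)


def session_to_json(session: Session, path=None) -> str:
    """Serialize a session to JSON; write to ``path`` when given."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session.session_id,
        "trials": [
            {
                "left_times": np.asarray(t.clicks.left_times).tolist(),
                "right_times": np.asarray(t.clicks.right_times).tolist(),
                "duration": t.clicks.duration,
                "choice": t.choice,
                "move_onset": t.move_onset,
                "start_time": t.start_time,
            }
            for t in session.trials
        ],
        "neuron_ids": list(session.neuron_ids),
        "spike_times": [
            [np.asarray(st).tolist() for st in per] for per in session.spike_times
        ],
    }
    if session.ground_truth is not None:
        doc["ground_truth"] = {
            "latents": [np.asarray(z).tolist() for z in session.ground_truth.latents],
            "commit_step": session.ground_truth.commit_step.tolist(),
            "commit_side": list(session.ground_truth.commit_side),
        }
    text = json.dumps(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def session_from_json(source) -> Session:
    """Load a session from a JSON string or file path."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SessionValidationError(
            f"unsupported schema version {doc.get('schema_version')}"
        )
    for key in ("trials", "neuron_ids", "spike_times"):
        if key not in doc:
            raise SessionValidationError(f"missing mandatory field '{key}'")
    trials = []
    for t in doc["trials"]:
        if "choice" not in t:
            raise SessionValidationError("missing mandatory field 'choice'")
        trials.append(
            TrialData(
                clicks=ClickTrain(
                    left_times=np.asarray(t["left_times"], dtype=float),
                    right_times=np.asarray(t["right_times"], dtype=float),
                    duration=float(t["duration"]),
                ),
                choice=t["choice"],
                move_onset=float(t["move_onset"]),
                start_time=float(t["start_time"]),
            )
        )
    spikes = [
        [np.asarray(st, dtype=float) for st in per] for per in doc["spike_times"]
    ]
    gt = None
    if "ground_truth" in doc:
        g = doc["ground_truth"]
        gt = GroundTruth(
            latents=[np.asarray(z, dtype=float) for z in g["latents"]],
            commit_step=np.asarray(g["commit_step"], dtype=int),
            commit_side=np.asarray(g["commit_side"], dtype=object),
        )
    return Session(
        session_id=doc.get("session_id", ""),
        trials=trials,
        neuron_ids=list(doc["neuron_ids"]),
        spike_times=spikes,
        ground_truth=gt,
    )
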