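"""Session data model and plain-text session-bundle I/O.

A recording session couples a trial table (pellet dispense, cooperation
onset, trial end, intertrial end), each monkey's binary button-push series
in 100 ms bins, the self-monkey's 30 Hz gaze track plus labelled object
tracks from the scene camera, timestamped social events, per-unit spike
times with electrode/area metadata, and per-unit waveform sample matrices.

On disk a bundle is a directory of uncompressed CSV files (one per table,
waveforms under ``waveforms/<unit_id>.csv``) plus ``config.json``.  Times
are integer milliseconds from session start; intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG

EVENT_KINDS = ("view_reward", "view_partner", "view_button", "view_random",
               "self_push", "partner_push")
FIXATION_KINDS = ("view_reward", "view_partner", "view_button", "view_random")
CHOICE_KINDS = ("self_push", "partner_push")
MONKEYS = ("self", "partner")
AREAS = ("V4", "dlPFC")


class BundleError(ValueError):
    """Raised for missing files or invariant violations in a session bundle."""


@dataclass(frozen=True)
class TrialWindow:
    trial_id: int
    t_start: int
    t_coop: int | None   # cooperation onset (both pushing); None if never
    t_end: int
    intertrial_end: int

    def __post_init__(self) -> None:
        if self.t_coop is not None and not (self.t_start < self.t_coop <= self.t_end):
            raise BundleError(
                f"trial {self.trial_id}: need t_start < t_coop <= t_end")
        if not (self.t_start < self.t_end < self.intertrial_end):
            raise BundleError(
                f"trial {self.trial_id}: need t_start < t_end < intertrial_end")


@dataclass(frozen=True)
class EventRecord:
    kind: str
    onset: int
    offset: int
    trial_id: int   # -1 marks an intertrial event

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise BundleError(f"unknown event kind {self.kind!r}")
        if self.offset < self.onset:
            raise BundleError(
                f"event {self.kind}@{self.onset}: offset < onset")

    @property
    def duration(self) -> int:
        return self.offset - self.onset

    @property
    def is_fixation(self) -> bool:
        return self.kind in FIXATION_KINDS


@dataclass(frozen=True)
class UnitMeta:
    unit_id: str
    electrode: int
    area: str
    unit_class: str  # "single" | "multi"

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise BundleError(f"unit {self.unit_id}: unknown area {self.area!r}")
        if self.unit_class not in ("single", "multi"):
            raise BundleError(f"unit {self.unit_id}: bad unit_class")


@dataclass(frozen=True)
class SpikeTrain:
    unit_id: str
    times: np.ndarray  # sorted spike times, ms

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) < 0)):
            raise BundleError(f"unit {self.unit_id}: spike times must be sorted 1-D")
        object.__setattr__(self, "times", t)


@dataclass
class GazeTrack:
    t: np.ndarray       # ms, 30 Hz spacing
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray   # crosshair present; invalid samples have x = y = 0

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise BundleError("gaze track columns differ in length")


@dataclass
class SessionBundle:
    session_index: int
    pair_id: str
    trials: list[TrialWindow]
    pushes: dict[str, np.ndarray]        # monkey -> session-long binary 100 ms bins
    gaze: GazeTrack | None
    objects: pd.DataFrame | None         # columns t, object, x_px, y_px
    events: list[EventRecord]
    spikes: list[SpikeTrain]
    units: list[UnitMeta]
    waveforms: dict[str, np.ndarray] = field(default_factory=dict)
    config: AnalysisConfig = DEFAULT_CONFIG

    def validate(self) -> "SessionBundle":
        if self.session_index < 1:
            raise BundleError("session_index must be >= 1")
        for prev, cur in zip(self.trials, self.trials[1:]):
            if cur.t_start < prev.intertrial_end:
                raise BundleError(
                    f"trials {prev.trial_id},{cur.trial_id} overlap or unordered")
        for m in self.pushes:
            if m not in MONKEYS:
                raise BundleError(f"unknown monkey {m!r} in pushes")
            vals = np.unique(self.pushes[m])
            if not np.all(np.isin(vals, (0, 1))):
                raise BundleError(f"push series for {m!r} is not binary")
        known = {u.unit_id for u in self.units}
        for st in self.spikes:
            if st.unit_id not in known:
                raise BundleError(f"spike train for unknown unit {st.unit_id!r}")
        for ev in self.events:
            if ev.is_fixation and ev.duration < self.config.fixation_min_ms:
                raise BundleError(
                    f"fixation event {ev.kind}@{ev.onset} shorter than "
                    f"{self.config.fixation_min_ms} ms")
            if not self._covers(ev.onset):
                raise BundleError(
                    f"event {ev.kind}@{ev.onset} outside all trial/intertrial windows")
        return self

    def _covers(self, t: int) -> bool:
        return any(tr.t_start <= t < tr.intertrial_end for tr in self.trials)

    def trial_of(self, t: int) -> TrialWindow | None:
        for tr in self.trials:
            if tr.t_start <= t < tr.intertrial_end:
                return tr
        return None

    def spike_train(self, unit_id: str) -> SpikeTrain:
        for st in self.spikes:
            if st.unit_id == unit_id:
                return st
        raise KeyError(unit_id)

    def units_in(self, area: str) -> list[UnitMeta]:
        return [u for u in self.units if u.area == area]

    def events_of(self, kind: str) -> list[EventRecord]:
        return [e for e in self.events if e.kind == kind]


# ---------------------------------------------------------------------------
# directory I/O

_REQUIRED = ("trials.csv", "pushes.csv", "events.csv", "spikes.csv", "units.csv")


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # malformed rows reported with file name
        raise BundleError(f"failed to parse {path.name}: {exc}") from exc


def read_session_bundle(path: str | Path,
                        config: AnalysisConfig | None = None) -> SessionBundle:
    """Read and fully validate a session-bundle directory.

    Missing required files and invariant violations raise ``BundleError``
    naming the offending file or record.
    """
    root = Path(path)
    if not root.is_dir():
        raise BundleError(f"bundle directory not found: {root}")
    for name in _REQUIRED:
        if not (root / name).exists():
            raise BundleError(f"missing required file {name!r} in {root}")

    meta = {}
    if (root / "config.json").exists():
        meta = json.loads((root / "config.json").read_text())
    cfg = config or DEFAULT_CONFIG

    trials_df = _read_csv(root / "trials.csv")
    trials = [TrialWindow(int(r.trial_id), int(r.t_start),
                          None if pd.isna(r.t_coop) else int(r.t_coop),
                          int(r.t_end), int(r.intertrial_end))
              for r in trials_df.itertuples()]

    pushes_df = _read_csv(root / "pushes.csv")
    pushes: dict[str, np.ndarray] = {}
    for monkey, grp in pushes_df.groupby("monkey"):
        grp = grp.sort_values("bin_index")
        n = int(grp.bin_index.max()) + 1
        series = np.zeros(n, dtype=np.int8)
        series[grp.bin_index.to_numpy()] = grp.value.to_numpy()
        pushes[str(monkey)] = series

    gaze = None
    if (root / "gaze.csv").exists():
        g = _read_csv(root / "gaze.csv")
        gaze = GazeTrack(t=g.t.to_numpy(float), x_px=g.x_px.to_numpy(float),
                         y_px=g.y_px.to_numpy(float),
                         valid=g.valid.to_numpy().astype(bool))

    objects = None
    if (root / "objects.csv").exists():
        objects = _read_csv(root / "objects.csv")

    events_df = _read_csv(root / "events.csv")
    events = [EventRecord(str(r.kind), int(r.onset), int(r.offset), int(r.trial_id))
              for r in events_df.itertuples()]

    units_df = _read_csv(root / "units.csv")
    units = [UnitMeta(str(r.unit_id), int(r.electrode), str(r.area),
                      str(r.unit_class)) for r in units_df.itertuples()]

    spikes_df = _read_csv(root / "spikes.csv")
    spikes = []
    for unit_id, grp in spikes_df.groupby("unit_id"):
        spikes.append(SpikeTrain(str(unit_id), np.sort(grp.t.to_numpy(float))))
    for u in units:  # silent units still get an (empty) train
        if not any(s.unit_id == u.unit_id for s in spikes):
            spikes.append(SpikeTrain(u.unit_id, np.array([])))

    waveforms = {}
    wf_dir = root / "waveforms"
    if wf_dir.is_dir():
        for f in sorted(wf_dir.glob("*.csv")):
            waveforms[f.stem] = np.loadtxt(f, delimiter=",", ndmin=2)

    bundle = SessionBundle(
        session_index=int(meta.get("session_index", 1)),
        pair_id=str(meta.get("pair_id", "pair1")),
        trials=trials, pushes=pushes, gaze=gaze, objects=objects,
        events=events, spikes=spikes, units=units, waveforms=waveforms,
        config=cfg)
    return bundle.validate()


def write_session_bundle(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a bundle as a directory of canonical CSV files (round-trip safe)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [{"trial_id": t.trial_id, "t_start": t.t_start,
          "t_coop": "" if t.t_coop is None else t.t_coop,
          "t_end": t.t_end, "intertrial_end": t.intertrial_end}
         for t in bundle.trials]).to_csv(root / "trials.csv", index=False)

    rows = []
    for monkey in sorted(bundle.pushes):
        for i, v in enumerate(bundle.pushes[monkey]):
            rows.append({"monkey": monkey, "bin_index": i, "value": int(v)})
    pd.DataFrame(rows).to_csv(root / "pushes.csv", index=False)

    if bundle.gaze is not None:
        pd.DataFrame({"t": bundle.gaze.t, "x_px": bundle.gaze.x_px,
                      "y_px": bundle.gaze.y_px,
                      "valid": bundle.gaze.valid.astype(int)}
                     ).to_csv(root / "gaze.csv", index=False)
    if bundle.objects is not None:
        bundle.objects.to_csv(root / "objects.csv", index=False)

    pd.DataFrame(
        [{"kind": e.kind, "onset": e.onset, "offset": e.offset,
          "trial_id": e.trial_id} for e in bundle.events]
    ).to_csv(root / "events.csv", index=False)

    spike_rows = []
    for st in sorted(bundle.spikes, key=lambda s: s.unit_id):
        for t in st.times:
            spike_rows.append({"unit_id": st.unit_id, "t": t})
    pd.DataFrame(spike_rows, columns=["unit_id", "t"]).to_csv(
        root / "spikes.csv", index=False)

    pd.DataFrame(
        [{"unit_id": u.unit_id, "electrode": u.electrode, "area": u.area,
          "unit_class": u.unit_class} for u in bundle.units]
    ).to_csv(root / "units.csv", index=False)

    if bundle.waveforms:
        wf_dir = root / "waveforms"
        wf_dir.mkdir(exist_ok=True)
        for unit_id, mat in sorted(bundle.waveforms.items()):
            np.savetxt(wf_dir / f"{unit_id}.csv", mat, delimiter=",", fmt="%.6g")

    (root / "config.json").write_text(json.dumps(
        {"session_index": bundle.session_index, "pair_id": bundle.pair_id},
        indent=0, sort_keys=True) + "\n")
    return root
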