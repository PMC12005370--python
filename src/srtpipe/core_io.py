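"""Domain types, tabular I/O, and configuration.

Times are stored in seconds. Behavioral event times are quantized to the
10 ms resolution of the task controller; spike times to 1 ms. Missing
events (no stimulus on probe/uncued trials, no poke on unrewarded trials)
are ``None`` in memory and empty fields on disk -- never sentinel numbers.

Trajectory coordinates live in an analysis space with y increasing
*upward*; readers convert image-row coordinates (y down) on request so
that "the highest point of the paw's path" is always ``max(y)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("srtpipe")

BEHAVIOR_RESOLUTION = 0.01  # s, task-controller event clock
SPIKE_RESOLUTION = 0.001  # s

CUE_KINDS = ("stimulus", "probe", "uncued")
TASKS = ("srt", "selftiming")
PHASES = ("Pre", "Post")
LESION_GROUPS = ("uMO", "bMO", "uDLS", "bDLS", "sham", "none")
REGIONS = ("MO", "DLS")
TRAJECTORY_KINDS = ("locomotor", "paw")


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class ValidationError(ValueError):
    """Loaded or constructed data violates a domain invariant."""


class ParameterError(ValueError):
    """A generator or analysis parameter is outside its support."""


def quantize(t: float | None, resolution: float = BEHAVIOR_RESOLUTION) -> float | None:
    """Round ``t`` to the given clock resolution (None passes through)."""
    if t is None:
        return None
    return round(round(t / resolution) * resolution, 6)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    """One behavioral trial on the session clock.

    ``fp`` is the foreperiod: the press-to-stimulus delay the animal must
    wait through. ``stim_time`` is absent when no stimulus was delivered
    (probe/uncued trials, or premature releases that aborted the trial
    before stimulus onset); ``poke_time`` is absent on unrewarded trials.
    """

    index: int
    press_time: float
    fp: float
    release_time: float
    stim_time: float | None = None
    poke_time: float | None = None
    cue_kind: str = "stimulus"
    task: str = "srt"

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError(f"trial {self.index}: negative index")
        if self.fp <= 0:
            raise ValidationError(f"trial {self.index}: fp must be positive")
        if self.cue_kind not in CUE_KINDS:
            raise ValidationError(f"trial {self.index}: unknown cue_kind {self.cue_kind!r}")
        if self.task not in TASKS:
            raise ValidationError(f"trial {self.index}: unknown task {self.task!r}")
        if self.release_time <= self.press_time:
            raise ValidationError(
                f"trial {self.index}: release_time {self.release_time} <= "
                f"press_time {self.press_time}"
            )
        if self.stim_time is not None:
            if abs(self.stim_time - (self.press_time + self.fp)) > BEHAVIOR_RESOLUTION / 2 + 1e-9:
                raise ValidationError(
                    f"trial {self.index}: stim_time {self.stim_time} != press + fp "
                    f"({self.press_time + self.fp}) within 10 ms"
                )
        if self.poke_time is not None and self.poke_time <= self.release_time:
            raise ValidationError(
                f"trial {self.index}: poke_time {self.poke_time} <= release_time"
            )

    @property
    def hold(self) -> float:
        """Hold duration: lever release minus lever press, seconds."""
        return round(self.release_time - self.press_time, 6)


@dataclass
class Session:
    """An ordered collection of trials from one rat on one day."""

    rat_id: str
    session_index: int
    phase: str  # Pre | Post
    post_ordinal: int  # sessions since lesion; 0 for Pre
    lesion_group: str
    task: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"session {self.session_index}: unknown phase {self.phase!r}")
        if self.lesion_group not in LESION_GROUPS:
            raise ValidationError(
                f"session {self.session_index}: unknown lesion_group {self.lesion_group!r}"
            )
        if self.task not in TASKS:
            raise ValidationError(f"session {self.session_index}: unknown task {self.task!r}")
        presses = [t.press_time for t in self.trials]
        if any(b <= a for a, b in zip(presses, presses[1:])):
            raise ValidationError(
                f"session {self.session_index}: trials not ordered by press_time"
            )

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit, seconds, sorted, 1 ms resolution."""

    unit_id: str
    region: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unit {self.unit_id}: unknown region {self.region!r}")
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if st.size and np.any(np.diff(st) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if st.size and np.max(np.abs(st - np.round(st / SPIKE_RESOLUTION) * SPIKE_RESOLUTION)) > 1e-9:
            raise ValidationError(f"unit {self.unit_id}: spike times off the 1 ms grid")

    def __len__(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class TrialEvents:
    """The four within-trial event anchors used for warping."""

    trial_index: int
    press: float
    stim: float
    release: float
    poke: float

    def __post_init__(self) -> None:
        if not (self.press < self.stim < self.release < self.poke):
            raise ValidationError(
                f"trial {self.trial_index}: events not strictly increasing "
                f"(press={self.press}, stim={self.stim}, "
                f"release={self.release}, poke={self.poke})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.press, self.stim, self.release, self.poke])


@dataclass
class Trajectory:
    """A tracked 2D point path at nominally 50 Hz, pixels, y-up."""

    kind: str
    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # px
    y: np.ndarray  # px, increases upward in analysis space
    frame_interval: float = 0.02
    anchor_event: str = "release"
    rat_id: str = ""
    session_index: int = 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in TRAJECTORY_KINDS:
            raise ValidationError(f"unknown trajectory kind {self.kind!r}")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValidationError("trajectory t/x/y length mismatch")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValidationError("trajectory times not strictly increasing")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - self.frame_interval) > 0.1 * self.frame_interval + 1e-9):
                raise ValidationError(
                    "frame interval deviates more than 10% from nominal "
                    f"{self.frame_interval} s"
                )

    def __len__(self) -> int:
        return int(self.t.size)

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def translated(self, dx: float, dy: float) -> "Trajectory":
        out = Trajectory(
            kind=self.kind, t=self.t.copy(), x=self.x + dx, y=self.y + dy,
            frame_interval=self.frame_interval, anchor_event=self.anchor_event,
            rat_id=self.rat_id, session_index=self.session_index,
            trial_index=self.trial_index,
        )
        return out


@dataclass
class StudyConfig:
    """All analysis parameters with the study's stated defaults, plus paths."""

    session_table: str = "sessions.csv"
    spike_table: str = "spikes.csv"
    event_table: str = "events.csv"
    trajectory_table: str = "trajectories.csv"
    output_dir: str = "results"
    seed: int = 0
    # behavior
    response_window: float = 0.6
    late_cutoff: float = 2.0
    rt_min: float = 0.1
    rt_max: float = 2.0
    mad_k: float = 10.0
    kde_bandwidth: float = 0.075
    kde_bin_width: float = 0.05
    g_step: float = 0.01
    pre_min_per_fp: int = 500
    post_min_per_fp: int = 200
    series_merge_threshold: int = 50
    retrieval_merge_threshold: int = 30
    # neural
    sdf_sigma: float = 0.020
    # kinematics
    grid_width: int = 800
    grid_height: int = 700
    cell_size_cm: float = 0.4
    smoothing_sigma_px: float = 25.0
    # inference
    n_perm: int = 10_000
    fdr_q: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "rat_id", "session_index", "phase", "post_ordinal", "lesion_group",
    "task", "trial_index", "press_time", "fp", "stim_time", "release_time",
    "poke_time", "cue_kind",
]
SPIKE_COLUMNS = ["unit_id", "region", "spike_time"]
EVENT_COLUMNS = ["unit_id", "trial_index", "press", "stim", "release", "poke"]
TRAJECTORY_COLUMNS = ["rat_id", "session_index", "trial_index", "kind", "t", "x", "y"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _opt(v: float) -> float | None:
    return None if pd.isna(v) else float(v)


def read_session_table(path: str | Path) -> list[Session]:
    """Read a sessions.csv into Sessions grouped by (rat_id, session_index).

    Event times are re-quantized to the 10 ms behavioral clock on load, so
    a write/read round trip is exact.
    """
    df = pd.read_csv(path)
    _require_columns(df, SESSION_COLUMNS, path)
    sessions: list[Session] = []
    for (rat_id, session_index), grp in df.groupby(["rat_id", "session_index"], sort=True):
        head = grp.iloc[0]
        trials = []
        for _, row in grp.sort_values("press_time").iterrows():
            try:
                trials.append(
                    Trial(
                        index=int(row["trial_index"]),
                        press_time=quantize(float(row["press_time"])),
                        fp=quantize(float(row["fp"])),
                        release_time=quantize(float(row["release_time"])),
                        stim_time=quantize(_opt(row["stim_time"])),
                        poke_time=quantize(_opt(row["poke_time"])),
                        cue_kind=str(row["cue_kind"]),
                        task=str(row["task"]),
                    )
                )
            except ValidationError as err:
                raise ValidationError(
                    f"{path}: rat {rat_id} session {session_index}: {err}"
                ) from err
        sessions.append(
            Session(
                rat_id=str(rat_id),
                session_index=int(session_index),
                phase=str(head["phase"]),
                post_ordinal=int(head["post_ordinal"]),
                lesion_group=str(head["lesion_group"]),
                task=str(head["task"]),
                trials=trials,
            )
        )
    return sessions


def write_session_table(sessions: Iterable[Session], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for tr in s.trials:
            rows.append(
                dict(
                    rat_id=s.rat_id, session_index=s.session_index, phase=s.phase,
                    post_ordinal=s.post_ordinal, lesion_group=s.lesion_group,
                    task=s.task, trial_index=tr.index, press_time=tr.press_time,
                    fp=tr.fp, stim_time=tr.stim_time, release_time=tr.release_time,
                    poke_time=tr.poke_time, cue_kind=tr.cue_kind,
                )
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False, float_format="%.2f")


def read_spike_table(
    spike_path: str | Path, event_path: str | Path
) -> tuple[list[SpikeTrain], dict[str, list[TrialEvents]]]:
    """Read spikes.csv and events.csv.

    Returns the spike trains and, per unit, the per-trial event anchors.
    Unsorted spike times are sorted on load with a logged warning; invalid
    event orderings raise.
    """
    sdf = pd.read_csv(spike_path)
    _require_columns(sdf, SPIKE_COLUMNS, spike_path)
    edf = pd.read_csv(event_path)
    _require_columns(edf, EVENT_COLUMNS, event_path)

    trains: list[SpikeTrain] = []
    for (unit_id, region), grp in sdf.groupby(["unit_id", "region"], sort=True):
        st = np.round(grp["spike_time"].to_numpy(dtype=float) / SPIKE_RESOLUTION) * SPIKE_RESOLUTION
        if np.any(np.diff(st) < 0):
            logger.warning("unit %s: spike times unsorted on disk; sorting", unit_id)
            st = np.sort(st)
        trains.append(SpikeTrain(unit_id=str(unit_id), region=str(region), spike_times=st))

    events: dict[str, list[TrialEvents]] = {}
    for _, row in edf.iterrows():
        ev = TrialEvents(
            trial_index=int(row["trial_index"]),
            press=float(row["press"]), stim=float(row["stim"]),
            release=float(row["release"]), poke=float(row["poke"]),
        )
        events.setdefault(str(row["unit_id"]), []).append(ev)
    return trains, events


def write_spike_table(
    trains: Iterable[SpikeTrain],
    events: dict[str, list[TrialEvents]],
    spike_path: str | Path,
    event_path: str | Path,
) -> None:
    srows = [
        dict(unit_id=tr.unit_id, region=tr.region, spike_time=t)
        for tr in trains
        for t in tr.spike_times
    ]
    pd.DataFrame(srows, columns=SPIKE_COLUMNS).to_csv(spike_path, index=False, float_format="%.3f")
    erows = [
        dict(unit_id=uid, trial_index=ev.trial_index, press=ev.press,
             stim=ev.stim, release=ev.release, poke=ev.poke)
        for uid, evs in events.items()
        for ev in evs
    ]
    pd.DataFrame(erows, columns=EVENT_COLUMNS).to_csv(event_path, index=False, float_format="%.3f")


def read_trajectory_table(path: str | Path, y_down: bool = False) -> list[Trajectory]:
    """Read trajectories.csv.

    With ``y_down=True`` the file stores image-row coordinates (y grows
    downward); they are negated on load so analysis space is y-up.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    out = []
    keys = ["rat_id", "session_index", "trial_index", "kind"]
    for (rat_id, session_index, trial_index, kind), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("t")
        y = grp["y"].to_numpy(dtype=float)
        out.append(
            Trajectory(
                kind=str(kind),
                t=grp["t"].to_numpy(dtype=float),
                x=grp["x"].to_numpy(dtype=float),
                y=-y if y_down else y,
                rat_id=str(rat_id),
                session_index=int(session_index),
                trial_index=int(trial_index),
            )
        )
    return out


def write_trajectory_table(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    rows = []
    for tr in trajectories:
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append(
                dict(rat_id=tr.rat_id, session_index=tr.session_index,
                     trial_index=tr.trial_index, kind=tr.kind, t=t, x=x, y=y)
            )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)
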