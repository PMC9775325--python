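"""Event-log data model and interval derivation for sentinel head-turn records.

A focal observation is an alternating stream of *head moves* (the head is in
motion, vision blurred) and *looks* (the head is still, oriented into one of
four 90-degree quadrants around the body axis).  This module reads and
validates such logs, derives per-look records (duration, quadrant mid-point
angle, preceding head-move duration) and extracts *return times*: how long the
gaze takes to come back to a reference quadrant after an excursion of one or
more looks into other quadrants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "ObservationMeta",
    "LookRecord",
    "ReturnTime",
    "EventLogError",
    "ValidationError",
    "StructureError",
    "QUADRANT_ANGLES",
    "FRAME_SECONDS",
    "STATUS_LEVELS",
    "read_event_log",
    "write_event_log",
    "validate_events",
    "derive_looks",
    "extract_return_times",
    "summarize_observation",
    "looks_to_frame",
    "returns_to_frame",
]

#: Mid-point angle (degrees) of each quadrant; 0 deg is the body's long axis,
#: angles increase clockwise viewed from above so quadrant 2 is the bird's right.
QUADRANT_ANGLES = {1: 0.0, 2: 90.0, 3: 180.0, 4: 270.0}

#: Video frame duration (seconds) of the original recordings.
FRAME_SECONDS = 0.033

STATUS_LEVELS = ("juvenile", "adult_male", "adult_female")


class EventLogError(ValueError):
    """Base class for event-log problems."""


class ValidationError(EventLogError):
    """An event violates an invariant (ordering, overlap, domain)."""


class StructureError(EventLogError):
    """The head-move/look alternation structure is broken."""


@dataclass(frozen=True)
class Event:
    obs_id: str
    kind: Literal["head_move", "look"]
    t_start: float
    t_end: float
    quadrant: int | None = None  # required for looks, absent for head moves

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class ObservationMeta:
    obs_id: str
    group_id: str
    individual_id: str
    status: str
    group_size: int
    duration: float

    def __post_init__(self) -> None:
        if self.status not in STATUS_LEVELS:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.group_size < 1:
            raise ValidationError("group_size must be >= 1")
        if not self.duration > 0:
            raise ValidationError("observation duration must be > 0")


@dataclass(frozen=True)
class LookRecord:
    obs_id: str
    look_index: int
    t_start: float
    duration: float
    quadrant: int
    angle: float
    headmove_duration: float  # NaN when the look opens the observation

    @property
    def has_headmove(self) -> bool:
        return not math.isnan(self.headmove_duration)


@dataclass(frozen=True)
class ReturnTime:
    obs_id: str
    r: float
    excursion_quadrants: tuple[int, ...]  # run-collapsed sequence of quadrants
    n_looks_in_excursion: int


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_events(events: Sequence[Event], *, frame: float | None = None) -> None:
    """Check the invariants of one observation's event list.

    Events must be strictly time-ordered, non-overlapping, alternating in
    kind, with positive durations; looks carry a quadrant in 1..4 and head
    moves none.  When ``frame`` is given every duration must respect the
    one-frame floor (up to numerical slack).
    """
    prev_end = -math.inf
    prev_kind: str | None = None
    for ev in events:
        if ev.t_end <= ev.t_start:
            raise ValidationError(
                f"{ev.obs_id}: event at t={ev.t_start} has t_end <= t_start"
            )
        if ev.t_start < prev_end - 1e-12:
            raise ValidationError(
                f"{ev.obs_id}: event at t={ev.t_start} overlaps the previous event"
            )
        if ev.kind not in ("head_move", "look"):
            raise ValidationError(f"{ev.obs_id}: unknown event kind {ev.kind!r}")
        if ev.kind == "look":
            if ev.quadrant not in (1, 2, 3, 4):
                raise ValidationError(
                    f"{ev.obs_id}: look at t={ev.t_start} has invalid quadrant"
                )
        elif ev.quadrant is not None:
            raise ValidationError(
                f"{ev.obs_id}: head move at t={ev.t_start} carries a quadrant"
            )
        if prev_kind is not None and ev.kind == prev_kind:
            raise StructureError(
                f"{ev.obs_id}: two consecutive {ev.kind} events at t={ev.t_start}"
            )
        if frame is not None and ev.duration < frame - 1e-9:
            raise ValidationError(
                f"{ev.obs_id}: event at t={ev.t_start} shorter than one frame"
            )
        prev_end = ev.t_end
        prev_kind = ev.kind


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_COLUMNS = [
    "obs_id", "group_id", "individual_id", "status", "group_size",
    "kind", "t_start", "t_end", "quadrant",
]


def read_event_log(
    path, *, strict: bool = True, frame: float | None = None
) -> tuple[dict[str, list[Event]], list[ObservationMeta]]:
    """Read an event-log CSV into per-observation event lists plus metadata.

    The CSV is denormalised: every row repeats the observation metadata
    (group, individual, status, group size).  ``strict=True`` raises on any
    invariant violation; ``strict=False`` drops offending rows with a warning.
    The observation duration is taken as the end time of its last event.
    """
    df = pd.read_csv(
        path,
        dtype={"obs_id": str, "group_id": str, "individual_id": str},
        float_precision="round_trip",  # bit-exact write/read cycles
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"event log is missing columns: {missing}")

    events: dict[str, list[Event]] = {}
    meta: list[ObservationMeta] = []
    for obs_id, sub in df.groupby("obs_id", sort=False):
        evs: list[Event] = []
        for line, row in enumerate(sub.itertuples(index=False), start=1):
            try:
                kind = str(row.kind)
                q = None
                if not (row.quadrant is None or (isinstance(row.quadrant, float) and math.isnan(row.quadrant))):
                    q = int(row.quadrant)
                evs.append(Event(str(obs_id), kind, float(row.t_start), float(row.t_end), q))
            except (TypeError, ValueError) as exc:
                raise EventLogError(
                    f"{obs_id}: malformed row {line}: {exc}"
                ) from exc
        evs.sort(key=lambda e: e.t_start)
        if strict:
            validate_events(evs, frame=frame)
        else:
            evs = _drop_invalid(evs, frame=frame)
        events[str(obs_id)] = evs
        first = sub.iloc[0]
        meta.append(
            ObservationMeta(
                obs_id=str(obs_id),
                group_id=str(first["group_id"]),
                individual_id=str(first["individual_id"]),
                status=str(first["status"]),
                group_size=int(first["group_size"]),
                duration=float(max(e.t_end for e in evs)) if evs else float("nan"),
            )
        )
    return events, meta


def _drop_invalid(events: list[Event], *, frame: float | None) -> list[Event]:
    kept: list[Event] = []
    for ev in events:
        try:
            validate_events(kept + [ev], frame=frame)
        except EventLogError as exc:
            warnings.warn(f"dropping invalid event: {exc}", stacklevel=3)
            continue
        kept.append(ev)
    return kept


def write_event_log(
    events: dict[str, list[Event]],
    meta: Iterable[ObservationMeta],
    path,
) -> None:
    """Write events + metadata to the denormalised event-log CSV."""
    meta_by_obs = {m.obs_id: m for m in meta}
    rows = []
    for obs_id, evs in events.items():
        m = meta_by_obs[obs_id]
        for ev in evs:
            rows.append(
                {
                    "obs_id": obs_id,
                    "group_id": m.group_id,
                    "individual_id": m.individual_id,
                    "status": m.status,
                    "group_size": m.group_size,
                    "kind": ev.kind,
                    "t_start": ev.t_start,
                    "t_end": ev.t_end,
                    "quadrant": ev.quadrant if ev.quadrant is not None else "",
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interval derivation
# ---------------------------------------------------------------------------

def derive_looks(events: Sequence[Event]) -> list[LookRecord]:
    """Turn one observation's alternating event list into LookRecords.

    The look duration is the look's own interval; the head-move duration is
    the immediately preceding head move (NaN when the observation opens with
    a look).  Quadrant mid-point angles follow :data:`QUADRANT_ANGLES`.
    """
    if not events:
        return []
    validate_events(events)
    obs_id = events[0].obs_id
    looks: list[LookRecord] = []
    prev_headmove: float = math.nan
    idx = 0
    for ev in events:
        if ev.kind == "head_move":
            prev_headmove = ev.duration
            continue
        looks.append(
            LookRecord(
                obs_id=obs_id,
                look_index=idx,
                t_start=ev.t_start,
                duration=ev.duration,
                quadrant=ev.quadrant,  # type: ignore[arg-type]
                angle=QUADRANT_ANGLES[ev.quadrant],  # type: ignore[index]
                headmove_duration=prev_headmove,
            )
        )
        idx += 1
        prev_headmove = math.nan
    return looks


def extract_return_times(
    looks: Sequence[LookRecord],
    reference_quadrant: int = 1,
    *,
    convention: Literal["onset", "headmove"] = "onset",
) -> list[ReturnTime]:
    """Extract completed excursion-and-return intervals relative to a quadrant.

    An excursion is a maximal run of looks outside ``reference_quadrant``
    that is preceded and followed by a reference-quadrant look.  Under the
    default ``onset`` convention the clock runs from the onset of the first
    non-reference look to the onset of the next reference look; under
    ``headmove`` both endpoints shift back to the start of the head move
    leading into that look (falling back to the onset when no head move was
    recorded).  Excursions still open when the observation ends are
    right-censored and not emitted.
    """
    if reference_quadrant not in (1, 2, 3, 4):
        raise ValueError("reference_quadrant must be in 1..4")
    if convention not in ("onset", "headmove"):
        raise ValueError(f"unknown return-time convention {convention!r}")
    if looks and not any(lk.quadrant == reference_quadrant for lk in looks):
        warnings.warn(
            f"no look in reference quadrant {reference_quadrant}; no return times",
            stacklevel=2,
        )
        return []

    def clock(lk: LookRecord) -> float:
        if convention == "headmove" and lk.has_headmove:
            return lk.t_start - lk.headmove_duration
        return lk.t_start

    out: list[ReturnTime] = []
    seen_reference = False
    excursion: list[LookRecord] = []
    for lk in looks:
        if lk.quadrant == reference_quadrant:
            if excursion:
                quads: list[int] = []
                for e in excursion:
                    if not quads or quads[-1] != e.quadrant:
                        quads.append(e.quadrant)
                out.append(
                    ReturnTime(
                        obs_id=lk.obs_id,
                        r=clock(lk) - clock(excursion[0]),
                        excursion_quadrants=tuple(quads),
                        n_looks_in_excursion=len(excursion),
                    )
                )
                excursion = []
            seen_reference = True
        elif seen_reference:
            excursion.append(lk)
    return out


def summarize_observation(
    looks: Sequence[LookRecord],
    returns: Sequence[ReturnTime],
    meta: ObservationMeta,
) -> dict:
    """Per-observation summary: look counts, medians, head-turn rate, occupancy.

    The head-turn rate is the number of recorded head moves per minute of
    observation; quadrant occupancy is the fraction of looks per quadrant.
    """
    if not looks:
        raise EventLogError(f"{meta.obs_id}: no looks to summarize")
    if not meta.duration > 0:
        raise EventLogError(f"{meta.obs_id}: zero-span observation")
    durations = np.array([lk.duration for lk in looks])
    n_moves = sum(lk.has_headmove for lk in looks)
    quads = np.array([lk.quadrant for lk in looks])
    occupancy = tuple(float(np.mean(quads == q)) for q in (1, 2, 3, 4))
    return {
        "obs_id": meta.obs_id,
        "n_looks": len(looks),
        "median_look_duration": float(np.median(durations)),
        "head_turn_rate_per_min": n_moves / (meta.duration / 60.0),
        "occupancy": occupancy,
        "n_returns": len(returns),
        "median_return_time": float(np.median([rt.r for rt in returns])) if returns else math.nan,
    }


# ---------------------------------------------------------------------------
# tabular views
# ---------------------------------------------------------------------------

def looks_to_frame(looks: Iterable[LookRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "obs_id": lk.obs_id,
                "look_index": lk.look_index,
                "t_start": lk.t_start,
                "duration": lk.duration,
                "quadrant": lk.quadrant,
                "angle": lk.angle,
                "headmove_duration": lk.headmove_duration,
            }
            for lk in looks
        ]
    )


def returns_to_frame(returns: Iterable[ReturnTime]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "obs_id": rt.obs_id,
                "r": rt.r,
                "excursion_quadrants": "-".join(map(str, rt.excursion_quadrants)),
                "n_looks_in_excursion": rt.n_looks_in_excursion,
            }
            for rt in returns
        ]
    )
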