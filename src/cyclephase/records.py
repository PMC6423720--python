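"""Domain records for single-cell cell-cycle phase measurements.

A cell's life is summarized by five event times — birth, S-phase onset,
S-phase end, mitosis start (nuclear envelope breakdown), and telophase —
which delimit the four phase durations G1, S, G2 and M.  Records are
kept in hours as continuous reals; frame-based measurements are converted
at ingest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger("cyclephase")

PHASES = ("G1", "S", "G2", "M")

#: Default acquisition interval: one frame every 10 minutes.
DEFAULT_FRAME_INTERVAL_H = 10.0 / 60.0

_EVENT_FIELDS = ("t_birth", "t_s_onset", "t_s_end", "t_m_start", "t_telophase")
_DURATION_FIELDS = ("d_g1", "d_s", "d_g2", "d_m")

#: Exact CSV header for phase tables.
CSV_COLUMNS = [
    "cell_id",
    "condition",
    "mother_id",
    "sister_id",
    "frame_interval_h",
    "t_birth_h",
    "t_s_onset_h",
    "t_s_end_h",
    "t_m_start_h",
    "t_telophase_h",
    "d_g1_h",
    "d_s_h",
    "d_g2_h",
    "d_m_h",
]

_FIELD_TO_COLUMN = {
    "t_birth": "t_birth_h",
    "t_s_onset": "t_s_onset_h",
    "t_s_end": "t_s_end_h",
    "t_m_start": "t_m_start_h",
    "t_telophase": "t_telophase_h",
    "d_g1": "d_g1_h",
    "d_s": "d_s_h",
    "d_g2": "d_g2_h",
    "d_m": "d_m_h",
}

_DURATION_TOL = 1e-9


class PhaseRecordError(ValueError):
    """A record violates a phase-measurement invariant."""


class PhaseTableFormatError(ValueError):
    """A CSV file does not carry the expected phase-table schema."""


@dataclass
class PhaseRecord:
    """One cell's event times and/or phase durations, in hours.

    Event times and durations are each optional as a group; when both are
    present they must be mutually consistent (durations equal consecutive
    event-time differences to 1e-9 h).
    """

    cell_id: str
    condition: str = ""
    mother_id: str | None = None
    sister_id: str | None = None
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H
    t_birth: float | None = None
    t_s_onset: float | None = None
    t_s_end: float | None = None
    t_m_start: float | None = None
    t_telophase: float | None = None
    d_g1: float | None = None
    d_s: float | None = None
    d_g2: float | None = None
    d_m: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    def event_times(self) -> tuple[float | None, ...]:
        return tuple(getattr(self, f) for f in _EVENT_FIELDS)

    def durations(self) -> dict[str, float | None]:
        return {"G1": self.d_g1, "S": self.d_s, "G2": self.d_g2, "M": self.d_m}

    def duration(self, phase: str) -> float | None:
        try:
            return self.durations()[phase]
        except KeyError:
            raise KeyError(f"unknown phase {phase!r}; expected one of {PHASES}")

    def has_events(self) -> bool:
        return all(t is not None for t in self.event_times())

    def has_durations(self, phases: Sequence[str] = PHASES) -> bool:
        return all(self.duration(p) is not None for p in phases)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.frame_interval is None or not self.frame_interval > 0:
            raise PhaseRecordError(
                f"{self.cell_id}: frame_interval must be > 0, got {self.frame_interval}"
            )
        events = self.event_times()
        if self.has_events():
            names = _EVENT_FIELDS
            for (na, ta), (nb, tb) in zip(zip(names, events), zip(names[1:], events[1:])):
                if tb < ta:
                    raise PhaseRecordError(
                        f"{self.cell_id}: non-monotone event times: {na}={ta} > {nb}={tb}"
                    )
        for name in _DURATION_FIELDS:
            d = getattr(self, name)
            if d is not None and not d > 0:
                raise PhaseRecordError(
                    f"{self.cell_id}: duration {name} must be strictly positive, got {d}"
                )
        # cross-check events vs durations when both present
        if self.has_events():
            expected = [events[i + 1] - events[i] for i in range(4)]
            for name, exp in zip(_DURATION_FIELDS, expected):
                d = getattr(self, name)
                if d is not None and abs(d - exp) > _DURATION_TOL:
                    raise PhaseRecordError(
                        f"{self.cell_id}: duration {name}={d} inconsistent with "
                        f"event times (expected {exp})"
                    )


def durations_from_events(rec: PhaseRecord) -> PhaseRecord:
    """Derive the four phase durations from the five event times.

    G1 = S onset − birth, S = S end − S onset, G2 = mitosis start − S end,
    M = telophase − mitosis start.  All five event times must be present
    and strictly increasing (a zero-length phase is rejected).
    """
    if not rec.has_events():
        missing = [f for f in _EVENT_FIELDS if getattr(rec, f) is None]
        raise PhaseRecordError(f"{rec.cell_id}: missing event times: {missing}")
    events = rec.event_times()
    names = _EVENT_FIELDS
    for i in range(4):
        if not events[i + 1] > events[i]:  # type: ignore[operator]
            raise PhaseRecordError(
                f"{rec.cell_id}: event times must be strictly increasing to yield "
                f"positive durations; {names[i]}={events[i]} vs {names[i + 1]}={events[i + 1]}"
            )
    return replace(
        rec,
        d_g1=events[1] - events[0],
        d_s=events[2] - events[1],
        d_g2=events[3] - events[2],
        d_m=events[4] - events[3],
    )


@dataclass
class PhaseTable:
    """Ordered collection of :class:`PhaseRecord` with unique cell ids."""

    records: list[PhaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[str, PhaseRecord] = {}
        for rec in self.records:
            if rec.cell_id in seen:
                raise PhaseRecordError(f"duplicate cell_id {rec.cell_id!r}")
            seen[rec.cell_id] = rec
        for rec in self.records:
            sid = rec.sister_id
            if sid is not None:
                if sid not in seen:
                    raise PhaseRecordError(
                        f"{rec.cell_id}: sister_id {sid!r} not present in table"
                    )
                if seen[sid].sister_id != rec.cell_id:
                    raise PhaseRecordError(
                        f"sister relation not symmetric: {rec.cell_id} <-> {sid}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PhaseRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PhaseRecord:
        return self.records[i]

    def by_id(self, cell_id: str) -> PhaseRecord:
        for rec in self.records:
            if rec.cell_id == cell_id:
                return rec
        raise KeyError(cell_id)

    def durations(self, phase: str, require: bool = True) -> list[float]:
        """Durations of one phase across all records (skipping absent ones)."""
        out = []
        for rec in self.records:
            d = rec.duration(phase)
            if d is not None:
                out.append(d)
            elif require:
                raise PhaseRecordError(f"{rec.cell_id}: phase {phase} duration absent")
        return out

    def sister_pairs(self) -> list[tuple[PhaseRecord, PhaseRecord]]:
        """Each sister pair once, in table order."""
        pairs, done = [], set()
        for rec in self.records:
            if rec.sister_id is not None and rec.cell_id not in done:
                sib = self.by_id(rec.sister_id)
                pairs.append((rec, sib))
                done.update((rec.cell_id, sib.cell_id))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "cell_id": rec.cell_id,
                "condition": rec.condition,
                "mother_id": rec.mother_id,
                "sister_id": rec.sister_id,
                "frame_interval_h": rec.frame_interval,
            }
            for f, col in _FIELD_TO_COLUMN.items():
                row[col] = getattr(rec, f)
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def read_phase_table(path: str | Path, derive_durations: bool = True) -> PhaseTable:
    """Read a phase table CSV.

    The file must carry the canonical header (see :data:`CSV_COLUMNS`) with
    at least ``cell_id`` plus either event-time or duration columns.  Rows
    violating record invariants are dropped with a logged reason.  When a
    row has all five event times but no durations, durations are derived.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"cell_id": str, "mother_id": str, "sister_id": str})
    except pd.errors.EmptyDataError:
        logger.warning("phase table %s is empty; returning empty table", path)
        return PhaseTable([])
    if "cell_id" not in df.columns:
        raise PhaseTableFormatError(
            f"{path}: missing mandatory column 'cell_id'; expected header {CSV_COLUMNS}"
        )
    have_events = all(c in df.columns for c in CSV_COLUMNS[5:10])
    have_durs = all(c in df.columns for c in CSV_COLUMNS[10:14])
    if not (have_events or have_durs):
        raise PhaseTableFormatError(
            f"{path}: need either event-time columns {CSV_COLUMNS[5:10]} or "
            f"duration columns {CSV_COLUMNS[10:14]}"
        )

    def _get(row, col, default=None):
        if col not in df.columns:
            return default
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return default
        return v

    records, n_rejected = [], 0
    for _, row in df.iterrows():
        kwargs = dict(
            cell_id=str(row["cell_id"]),
            condition=str(_get(row, "condition", "") or ""),
            mother_id=_get(row, "mother_id"),
            sister_id=_get(row, "sister_id"),
            frame_interval=float(
                _get(row, "frame_interval_h", DEFAULT_FRAME_INTERVAL_H)
            ),
        )
        for f, col in _FIELD_TO_COLUMN.items():
            v = _get(row, col)
            kwargs[f] = float(v) if v is not None else None
        try:
            rec = PhaseRecord(**kwargs)
            if derive_durations and rec.has_events() and not rec.has_durations():
                rec = durations_from_events(rec)
            records.append(rec)
        except PhaseRecordError as exc:
            n_rejected += 1
            logger.warning("rejected row %s: %s", kwargs.get("cell_id"), exc)
    if n_rejected:
        logger.warning("%s: rejected %d invalid rows", path, n_rejected)
    return PhaseTable(records)


def write_phase_table(table: PhaseTable, path: str | Path) -> None:
    """Write a phase table to CSV (canonical header; absent fields empty)."""
    df = table.to_frame()
    df.to_csv(path, index=False)


def table_from_durations(
    durations: Iterable[dict[str, float]],
    condition: str = "",
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H,
    id_prefix: str = "cell",
) -> PhaseTable:
    """Build a table from per-cell ``{phase: duration}`` mappings."""
    records = []
    for i, d in enumerate(durations):
        records.append(
            PhaseRecord(
                cell_id=f"{id_prefix}{i:05d}",
                condition=condition,
                frame_interval=frame_interval,
                d_g1=d.get("G1"),
                d_s=d.get("S"),
                d_g2=d.get("G2"),
                d_m=d.get("M"),
            )
        )
    return PhaseTable(records)
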