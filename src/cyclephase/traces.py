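"""Phase-boundary detection from 1-D single-cell reporter traces.

Two reporter read-outs are supported:

* ``pcna_variance`` — the spatial variance of a PCNA reporter, which is
  low in G1, high during S (punctate foci) and low again in G2; S-phase
  onset/end are low→high and high→low transitions of the 1-D signal.
* ``pip_mvenus`` — a PIP-degron reporter that is high in G1, rapidly
  degraded during S, and re-accumulates in G2.  S onset is the point of
  50% loss of the G1 level; G2 onset is a rise of 2% of the maximum
  signal above the S-phase level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PCNA_VARIANCE = "pcna_variance"
PIP_MVENUS = "pip_mvenus"


@dataclass
class TraceSeries:
    """Time-indexed 1-D reporter signal for one cell."""

    cell_id: str
    frame_interval: float  # hours per frame
    signal: np.ndarray
    kind: str = PCNA_VARIANCE

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size < 3:
            raise ValueError("trace needs at least 3 frames")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.kind not in (PCNA_VARIANCE, PIP_MVENUS):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return int(self.signal.size)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class EventCalls:
    """Called phase-boundary frames for one trace (0-based, half-open:
    the onset frame is the first frame inside the new phase)."""

    cell_id: str
    s_onset_frame: int | None = None
    s_end_frame: int | None = None  # pcna: S end; pip: G2 onset
    no_call_reason: str | None = None

    def __post_init__(self) -> None:
        if (
            self.s_onset_frame is not None
            and self.s_end_frame is not None
            and not self.s_onset_frame < self.s_end_frame
        ):
            raise ValueError("onset frame must precede end frame")

    @property
    def called(self) -> bool:
        return self.s_onset_frame is not None and self.s_end_frame is not None


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed trace keeps its length and edges
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return sm


def _sustained_crossing(
    x: np.ndarray, threshold: float, upward: bool, start: int = 0, sustain: int = 2
) -> int | None:
    """First index >= start where x crosses threshold and stays there for
    ``sustain`` consecutive frames."""
    above = x > threshold if upward else x < threshold
    for i in range(start, x.size - sustain + 1):
        if above[i : i + sustain].all():
            return i
    return None


def call_s_phase_pcna(trace: TraceSeries, smoothing_window: int = 3) -> EventCalls:
    """Call S-phase onset and end from a PCNA-variance trace.

    The signal is smoothed with a moving average; low/high plateau
    levels are taken as the lower/upper quartiles of the smoothed trace
    and the midpoint between them is the crossing threshold.  Onset is
    the first upward crossing sustained for two frames, end the first
    subsequent sustained downward crossing.  Affine rescaling of the
    signal leaves the calls unchanged.
    """
    if trace.kind != PCNA_VARIANCE:
        raise ValueError(f"expected a {PCNA_VARIANCE} trace, got {trace.kind}")
    sm = _moving_average(trace.signal, smoothing_window)
    low, high = np.percentile(sm, [25, 75])
    if high - low <= 1e-12 * max(abs(high), 1.0):
        return EventCalls(trace.cell_id, no_call_reason="flat trace (no dynamic range)")
    mid = 0.5 * (low + high)
    onset = _sustained_crossing(sm, mid, upward=True)
    if onset is None:
        return EventCalls(trace.cell_id, no_call_reason="no sustained upward crossing")
    end = _sustained_crossing(sm, mid, upward=False, start=onset + 1)
    if end is None:
        return EventCalls(
            trace.cell_id,
            s_onset_frame=int(onset),
            no_call_reason="no sustained downward crossing after onset",
        )
    return EventCalls(trace.cell_id, s_onset_frame=int(onset), s_end_frame=int(end))


def call_phases_pip(trace: TraceSeries, sustain: int = 2) -> EventCalls:
    """Call S onset and G2 onset from a PIP-degron reporter trace.

    S onset: first frame where the signal falls below 50% of the G1
    level; G2 onset: first subsequent frame where it rises by more than
    2% of the trace maximum above the S-phase level.  Plateau levels are
    medians of the segments delimited by the crossings themselves
    (two passes: provisional crossing → refined level → final crossing).
    """
    if trace.kind != PIP_MVENUS:
        raise ValueError(f"expected a {PIP_MVENUS} trace, got {trace.kind}")
    sig = trace.signal
    # pass 1: provisional G1 level from the leading frames
    g1_prov = float(np.median(sig[: min(3, sig.size)]))
    onset = _sustained_crossing(sig, 0.5 * g1_prov, upward=False, sustain=sustain)
    if onset is None or onset == 0:
        return EventCalls(
            trace.cell_id, no_call_reason="signal never drops below 50% of G1 level"
        )
    # pass 2: refine the G1 level over the pre-onset plateau and re-call
    g1_level = float(np.median(sig[:onset]))
    onset = _sustained_crossing(sig, 0.5 * g1_level, upward=False, sustain=sustain)
    if onset is None or onset == 0:
        return EventCalls(
            trace.cell_id, no_call_reason="signal never drops below 50% of G1 level"
        )
    # provisional S level from the low quartile after onset, then refine;
    # the upward search must begin on the S plateau (below threshold), not
    # while the signal is still falling through the threshold from above
    post = sig[onset:]
    s_prov = float(np.percentile(post, 25))
    thr = s_prov + 0.02 * float(np.max(sig))

    def _rise_after_plateau(threshold: float) -> int | None:
        below = np.flatnonzero(sig[onset:] < threshold)
        if below.size == 0:
            return None
        start = onset + int(below[0])
        return _sustained_crossing(sig, threshold, upward=True, start=start,
                                   sustain=sustain)

    g2 = _rise_after_plateau(thr)
    if g2 is not None:
        s_level = float(np.median(sig[onset:g2])) if g2 > onset else s_prov
        thr = s_level + 0.02 * float(np.max(sig))
        g2 = _rise_after_plateau(thr)
    if g2 is None:
        return EventCalls(
            trace.cell_id,
            s_onset_frame=int(onset),
            no_call_reason="no rise above S-phase level",
        )
    return EventCalls(trace.cell_id, s_onset_frame=int(onset), s_end_frame=int(g2))


def call_traces(traces, kind: str | None = None, **kwargs) -> list[EventCalls]:
    """Apply the appropriate caller to each trace."""
    out = []
    for tr in traces:
        k = kind or tr.kind
        if k == PCNA_VARIANCE:
            out.append(call_s_phase_pcna(tr, **kwargs))
        else:
            out.append(call_phases_pip(tr, **kwargs))
    return out


def evaluate_calls(calls, truth: pd.DataFrame) -> dict:
    """Compare calls with a ground-truth table.

    ``truth`` must have columns cell_id, s_onset_frame, s_end_frame.
    Returns per-event frame errors, the fraction of events within ±1
    frame, and the no-call rate.
    """
    truth = truth.set_index(truth["cell_id"].astype(str))
    unmatched = [c.cell_id for c in calls if str(c.cell_id) not in truth.index]
    if unmatched:
        raise KeyError(f"calls without ground truth: {unmatched}")
    errors = []
    n_events = 0
    n_no_call = 0
    for c in calls:
        row = truth.loc[str(c.cell_id)]
        for called, true_col in (
            (c.s_onset_frame, "s_onset_frame"),
            (c.s_end_frame, "s_end_frame"),
        ):
            n_events += 1
            if called is None:
                n_no_call += 1
            else:
                errors.append(int(called) - int(row[true_col]))
    errors = np.asarray(errors, dtype=int)
    within_1 = float(np.mean(np.abs(errors) <= 1)) if errors.size else 0.0
    return {
        "frame_errors": errors,
        "fraction_within_1": within_1,
        "no_call_rate": n_no_call / n_events if n_events else 0.0,
        "mean_error": float(np.mean(errors)) if errors.size else float("nan"),
        "n_events": n_events,
    }


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_traces(traces, path: str | Path) -> None:
    rows = []
    for tr in traces:
        t = tr.times()
        for f in range(tr.n_frames):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": f,
                    "time_h": t[f],
                    "signal": tr.signal[f],
                    "kind": tr.kind,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path: str | Path, frame_interval: float | None = None) -> list[TraceSeries]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        if frame_interval is None:
            t = grp["time_h"].to_numpy()
            dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        else:
            dt = frame_interval
        kind = str(grp["kind"].iloc[0]) if "kind" in grp else PCNA_VARIANCE
        out.append(
            TraceSeries(
                cell_id=str(cid),
                frame_interval=dt,
                signal=grp["signal"].to_numpy(),
                kind=kind,
            )
        )
    return out


def write_calls(calls, frame_interval: float, path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "cell_id": c.cell_id,
                "s_onset_frame": c.s_onset_frame,
                "s_end_frame": c.s_end_frame,
                "s_onset_h": None
                if c.s_onset_frame is None
                else c.s_onset_frame * frame_interval,
                "s_end_h": None
                if c.s_end_frame is None
                else c.s_end_frame * frame_interval,
                "no_call_reason": c.no_call_reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
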