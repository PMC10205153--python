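"""Stop-signal task analytics: screening and SSRT by the integration method.

SSRT = the go-RT distribution value at the stop-failure rate, minus the
mean stop-signal delay. Go omissions are replaced by the maximum observed
go RT before ranking (integration-with-replacement); the rank convention
is ceil(p * n) with no interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StopSignalSession",
    "ScreenReport",
    "screen_session",
    "ssrt_integration",
    "stop_signal_summary",
    "read_session_tsv",
]


@dataclass
class StopSignalSession:
    """go_trials: RT in ms or None (omission); stop_trials: (ssd, responded, rt)."""

    participant_id: str
    go_trials: list  # float | None
    stop_trials: list  # (ssd_ms, responded: bool, rt_ms | None)

    def __post_init__(self):
        for ssd, responded, rt in self.stop_trials:
            if not (50.0 <= ssd <= 1000.0):
                raise ValueError(f"SSD {ssd} outside [50, 1000] ms")
            if responded and (rt is None or rt <= 0):
                raise ValueError("responded stop trial needs a positive RT")

    @property
    def p_respond_stop(self) -> float:
        if not self.stop_trials:
            raise ValueError("no stop trials")
        return float(np.mean([r for _, r, _ in self.stop_trials]))

    @property
    def mean_ssd(self) -> float:
        return float(np.mean([s for s, _, _ in self.stop_trials]))

    @property
    def p_omission_go(self) -> float:
        if not self.go_trials:
            raise ValueError("no go trials")
        return float(np.mean([rt is None for rt in self.go_trials]))


@dataclass
class ScreenReport:
    participant_id: str
    exclude: bool
    caution: bool
    p_respond_stop: float | None
    go_stop_rt_gap_sd: float | None
    notes: list[str] = field(default_factory=list)


def screen_session(session: StopSignalSession) -> ScreenReport:
    """Exclude when mean go RT is > 2 SD away from the stop-trial RTs;
    flag caution when p(respond|stop) falls outside [0.25, 0.75]."""
    if not session.go_trials or not session.stop_trials:
        raise ValueError("need at least one go and one stop trial")
    go_rts = [rt for rt in session.go_trials if rt is not None]
    stop_rts = [rt for _, r, rt in session.stop_trials if r and rt is not None]
    notes = []
    exclude = False
    gap_sd = None
    if not stop_rts:
        notes.append("no responded stop trials; exclusion rule not evaluable")
        p = session.p_respond_stop
        return ScreenReport(session.participant_id, False, True, p, None, notes)
    stop_sd = float(np.std(stop_rts, ddof=0))
    gap = abs(float(np.mean(go_rts)) - float(np.mean(stop_rts)))
    if stop_sd > 0:
        gap_sd = gap / stop_sd
    else:
        gap_sd = 0.0 if gap == 0 else math.inf
    if gap_sd > 2.0:
        exclude = True
        notes.append(f"mean go RT {gap_sd:.1f} SD from stop-trial RTs")
    p = session.p_respond_stop
    caution = not (0.25 <= p <= 0.75)
    if caution:
        notes.append(f"p(respond|stop)={p:.2f} outside [0.25, 0.75]")
    return ScreenReport(session.participant_id, exclude, caution, p, gap_sd, notes)


def ssrt_integration(session: StopSignalSession) -> float:
    """Integration-method SSRT in ms.

    Omitted go trials are replaced by the maximum observed go RT, the go
    RTs sorted, and the RT at rank ceil(p(respond|stop) * n_go) taken
    (first occurrence at ties); SSRT is that RT minus the mean SSD.
    """
    p = session.p_respond_stop
    if p == 0.0:
        raise ValueError("SSRT undefined at zero response rate")
    go = [rt for rt in session.go_trials if rt is not None]
    if not go:
        raise ValueError("no observed go RTs")
    max_rt = max(go)
    filled = sorted((rt if rt is not None else max_rt) for rt in session.go_trials)
    n = len(filled)
    rank = min(math.ceil(p * n), n)
    nth_rt = filled[rank - 1]
    return float(nth_rt - session.mean_ssd)


def stop_signal_summary(sessions) -> pd.DataFrame:
    """Cohort means with normal-approximation 95% CIs.

    Covers p(omission|go), p(respond|stop), mean SSD, SSRT, go RT and
    stop-trial RT. With a single session the CI collapses to the point.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("need at least one session")
    per = []
    for s in sessions:
        go_rts = [rt for rt in s.go_trials if rt is not None]
        stop_rts = [rt for _, r, rt in s.stop_trials if r and rt is not None]
        rep = screen_session(s)
        if rep.exclude:
            warnings.warn(f"session {s.participant_id} fails screening; included in summary")
        per.append(
            {
                "p_omission_go": s.p_omission_go,
                "p_respond_stop": s.p_respond_stop,
                "mean_ssd": s.mean_ssd,
                "ssrt": ssrt_integration(s),
                "go_rt": float(np.mean(go_rts)) if go_rts else np.nan,
                "stop_rt": float(np.mean(stop_rts)) if stop_rts else np.nan,
            }
        )
    df = pd.DataFrame(per)
    n = len(df)
    rows = []
    for col in df.columns:
        vals = df[col].dropna().to_numpy()
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {"measure": col, "mean": mean, "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se}
        )
    return pd.DataFrame(rows).set_index("measure")


def read_session_tsv(path, participant_id: str | None = None) -> StopSignalSession:
    """TSV with columns trial_type {go,stop}, rt_ms (blank = omission),
    ssd_ms, responded."""
    df = pd.read_csv(path, sep="\t")
    go, stop = [], []
    for r in df.itertuples():
        if r.trial_type == "go":
            go.append(None if pd.isna(r.rt_ms) else float(r.rt_ms))
        elif r.trial_type == "stop":
            responded = bool(r.responded)
            stop.append(
                (float(r.ssd_ms), responded, float(r.rt_ms) if responded else None)
            )
        else:
            raise ValueError(f"unknown trial_type {r.trial_type!r}")
    pid = participant_id or str(getattr(df, "participant_id", "p000"))
    return StopSignalSession(participant_id=pid, go_trials=go, stop_trials=stop)
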