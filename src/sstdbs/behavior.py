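"""Behavioral indices of the stop-signal task.

Per-session summaries: mean RT per trial class (GORT, GCRT, GFRT, USRT),
mean stop-signal delay, SSRT by the integration method, the preparation
cost (PC = GORT - GFRT, proactive inhibition) and the oddball effect
(OE = GCRT - GORT, rare-cue context cost), plus stop-success and task-error
rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task_sim import Session, TrialType

__all__ = [
    "BehaviorSummary",
    "estimate_ssrt",
    "summarize_session",
    "cohort_behavior",
]


@dataclass
class BehaviorSummary:
    """Behavioral indices of one session; fields are ``None`` (not zero)
    when the trials needed to compute them are absent."""

    subject_id: str
    condition: str
    gort: float | None
    gcrt: float | None
    gfrt: float | None
    usrt: float | None
    mean_ssd: float | None
    ssrt: float | None
    pc: float | None
    oe: float | None
    stop_success_rate: float | None
    error_rate: float
    n_trials: dict[str, int] = field(default_factory=dict)


def estimate_ssrt(
    go_rts: Sequence[float], mean_ssd: float, p_respond: float
) -> float:
    """Integration-method SSRT estimate.

    Under the race model the probability of responding on a stop trial
    equals the mass of the go finishing-time distribution faster than
    SSD + SSRT, so the SSRT is estimated as the ``p_respond`` quantile of
    the go RT distribution (the ceil(p*n)-th order statistic) minus the mean
    SSD.  A negative estimate is returned as-is with a warning (it signals a
    violated race assumption or unstable tracking, not a computable latency).
    """
    go_rts = np.asarray(list(go_rts), dtype=float)
    if go_rts.size == 0:
        raise ValueError("go_rts must be non-empty")
    if not 0.0 < p_respond < 1.0:
        raise ValueError(f"p_respond must lie strictly in (0, 1), got {p_respond}")
    order = np.sort(go_rts)
    k = int(np.ceil(p_respond * order.size))  # 1-based order statistic
    quantile = float(order[k - 1])
    ssrt = quantile - float(mean_ssd)
    if ssrt <= 0:
        warnings.warn(
            f"non-positive SSRT estimate ({ssrt:.1f} ms); race-model "
            "assumptions or SSD tracking may be violated",
            stacklevel=2,
        )
    return ssrt


def _mean_rt(session: Session, trial_type: TrialType) -> tuple[float | None, int]:
    rts = [t.rt for t in session.of_type(trial_type) if t.responded and t.rt is not None]
    if not rts:
        return None, 0
    return float(np.mean(rts)), len(rts)


def summarize_session(session: Session) -> BehaviorSummary:
    """All behavioral indices of one session.

    RT means use responded trials only; omitted go-family trials enter the
    error rate but are excluded from the go finishing-time distribution used
    for the SSRT (at the simulator's <4% omission rate the exclusion variant
    is immaterial).
    """
    gort, n_go = _mean_rt(session, TrialType.GO)
    gcrt, n_gc = _mean_rt(session, TrialType.GO_CERTAIN)
    gfrt, n_gf = _mean_rt(session, TrialType.GO_FAST)
    usrt, n_us = _mean_rt(session, TrialType.STOP)

    stops = session.of_type(TrialType.STOP)
    mean_ssd = float(np.mean([t.ssd for t in stops])) if stops else None
    stop_success_rate = (
        float(np.mean([t.stop_success for t in stops])) if stops else None
    )

    go_family = [
        t
        for t in session.trials
        if t.trial_type in (TrialType.GO, TrialType.GO_FAST, TrialType.GO_CERTAIN)
    ]
    error_rate = (
        float(np.mean([not t.responded for t in go_family])) if go_family else 0.0
    )

    ssrt = None
    go_rts = [t.rt for t in session.of_type(TrialType.GO) if t.rt is not None]
    if stops and go_rts and stop_success_rate is not None:
        p_respond = 1.0 - stop_success_rate
        if 0.0 < p_respond < 1.0:
            ssrt = estimate_ssrt(go_rts, mean_ssd, p_respond)

    pc = gort - gfrt if gort is not None and gfrt is not None else None
    oe = gcrt - gort if gcrt is not None and gort is not None else None

    return BehaviorSummary(
        subject_id=session.subject_id,
        condition=session.condition,
        gort=gort,
        gcrt=gcrt,
        gfrt=gfrt,
        usrt=usrt,
        mean_ssd=mean_ssd,
        ssrt=ssrt,
        pc=pc,
        oe=oe,
        stop_success_rate=stop_success_rate,
        error_rate=error_rate,
        n_trials={
            "GO": n_go,
            "GO_CERTAIN": n_gc,
            "GO_FAST": n_gf,
            "STOP": len(stops),
            "US": n_us,
        },
    )


_SUMMARY_COLUMNS = [
    "subject_id", "condition", "gort", "gcrt", "gfrt", "usrt",
    "mean_ssd", "ssrt", "pc", "oe", "stop_success_rate", "error_rate",
]


def cohort_behavior(sessions: Iterable[Session]) -> pd.DataFrame:
    """One summary row per session, keyed by (subject, condition).

    The wide layout joins directly for paired ON/OFF statistics.  Duplicate
    (subject, condition) keys are an integrity error.
    """
    rows = []
    for s in sessions:
        summ = summarize_session(s)
        rows.append({c: getattr(summ, c) for c in _SUMMARY_COLUMNS})
    if not rows:
        raise ValueError("cohort_behavior needs at least one session")
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    dup = df.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        keys = df.loc[dup, ["subject_id", "condition"]].itertuples(index=False)
        raise ValueError(
            "duplicate (subject, condition) sessions: "
            + ", ".join(f"{k.subject_id}/{k.condition}" for k in keys)
        )
    return df
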