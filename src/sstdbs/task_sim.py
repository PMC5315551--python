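"""Synthetic stop-signal-task sessions and multichannel EEG epochs.

The behavioral generator implements the independent horse-race model: on
every STOP trial an ex-Gaussian Go finishing time races a normally
distributed Stop finishing time triggered at the stop-signal delay (SSD).
The SSD follows the task's one-up/one-down +/-50 ms staircase, which drives
stop-trial success toward 50%.  Four trial types are produced: GO, STOP,
GO_FAST (go cues never followed by a stop signal, probing proactive
inhibition release) and GO_CERTAIN (blocks of certain go cues, probing the
oddball cost of rare stop cues).

The EEG generator projects Gaussian-bump evoked components (N100, N200, P300
locked to the stop cue; a motor component locked to the go cue) through
fixed scalp topographies on a 96-channel 10-10 montage and adds white
Gaussian noise, keeping the noiseless inhibition-related part alongside the
data as ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TrialType",
    "TaskConfig",
    "RaceParams",
    "TrialRecord",
    "Session",
    "ErpComponent",
    "ErpTemplates",
    "EEGEpochs",
    "build_trial_sequence",
    "simulate_session",
    "simulate_cohort",
    "simulate_stop_outcomes",
    "default_templates",
    "default_channel_labels",
    "synthesize_eeg",
]


class InvalidConfigError(ValueError):
    """Raised when a task or race configuration violates its invariants."""


class TrialType(str, Enum):
    GO = "GO"
    STOP = "STOP"
    GO_FAST = "GO_FAST"
    GO_CERTAIN = "GO_CERTAIN"


#: Trial mix: the task fixes GO at 52.6% and keeps STOP rare (<16%); the
#: remaining mass is split evenly between the GO_FAST and GO_CERTAIN variants.
DEFAULT_PROPORTIONS: dict[TrialType, float] = {
    TrialType.GO: 0.526,
    TrialType.STOP: 0.158,
    TrialType.GO_FAST: 0.158,
    TrialType.GO_CERTAIN: 0.158,
}

#: Go responses slower than this deadline count as task errors (omissions).
RESPONSE_DEADLINE_MS = 1200.0


@dataclass(frozen=True)
class TaskConfig:
    """Design of one recording session.

    Times are in milliseconds.  ``proportions`` gives the per-block trial mix
    and must sum to 1; the STOP fraction is capped at 0.16 as in the task
    design (rare stop cues discourage waiting strategies).
    """

    n_blocks: int = 3
    trials_per_block: int = 100
    proportions: Mapping[TrialType, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    staircase_step: float = 50.0
    initial_ssd: float = 300.0
    ssd_bounds: tuple[float, float] = (50.0, 900.0)
    seed: int = 0

    def __post_init__(self) -> None:
        props = {TrialType(k): float(v) for k, v in self.proportions.items()}
        object.__setattr__(self, "proportions", props)
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"trial proportions sum to {total}, not 1")
        if any(v < 0 for v in props.values()):
            raise InvalidConfigError("trial proportions must be non-negative")
        if props.get(TrialType.STOP, 0.0) > 0.16 + 1e-12:
            raise InvalidConfigError("STOP fraction must be <= 0.16")
        if self.staircase_step <= 0:
            raise InvalidConfigError("staircase_step must be positive")
        if self.ssd_bounds[0] < 0 or self.ssd_bounds[1] <= self.ssd_bounds[0]:
            raise InvalidConfigError("ssd_bounds must satisfy 0 <= lo < hi")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise InvalidConfigError("need at least one block and one trial")


@dataclass(frozen=True)
class RaceParams:
    """Generative parameters of the Go and Stop processes (ms).

    Go finishing times are ex-Gaussian (mu, sigma, tau); the Stop process
    finishing time is ``ssd + s`` with ``s ~ Normal(ssrt_true, ssrt_sd)``
    truncated at zero.  ``p_trigger_failure`` is the probability that the
    stop process never starts, in which case the go response always escapes.
    ``gf_offset``/``gc_offset`` shift go RTs on GO_FAST/GO_CERTAIN trials and
    carry the preparation-cost and oddball-effect structure.
    """

    go_mu: float = 450.0
    go_sigma: float = 60.0
    go_tau: float = 200.0
    ssrt_true: float = 190.0
    ssrt_sd: float = 25.0
    p_trigger_failure: float = 0.02
    gf_offset: float = -85.0
    gc_offset: float = 58.0

    def __post_init__(self) -> None:
        if self.go_sigma <= 0 or self.go_tau < 0:
            raise InvalidConfigError("require go_sigma > 0 and go_tau >= 0")
        if self.ssrt_true <= 0:
            raise InvalidConfigError("ssrt_true must be positive")
        if not 0.0 <= self.p_trigger_failure <= 1.0:
            raise InvalidConfigError("p_trigger_failure must lie in [0, 1]")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.  ``ssd`` and ``stop_success`` exist on STOP
    trials only; ``rt`` exists iff the subject responded."""

    index: int
    block: int
    trial_type: TrialType
    ssd: float | None = None
    responded: bool = False
    rt: float | None = None
    stop_success: bool | None = None


@dataclass
class Session:
    """All trials of one subject in one stimulation condition."""

    subject_id: str
    condition: str  # "ON" or "OFF"
    trials: list[TrialRecord]
    config: TaskConfig
    params: RaceParams

    def __post_init__(self) -> None:
        expected = self.config.n_blocks * self.config.trials_per_block
        if len(self.trials) != expected:
            raise InvalidConfigError(
                f"session has {len(self.trials)} trials, expected {expected}"
            )

    def of_type(self, trial_type: TrialType) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type == trial_type]


def _allocate_block(proportions: Mapping[TrialType, float], n: int) -> dict[TrialType, int]:
    """Deterministic largest-remainder allocation of ``n`` trials.

    Agrees with round(p * n) whenever plain rounding fills the block exactly
    (e.g. 52.6% of 1000 -> 526); otherwise the leftover trials go to the
    types with the largest fractional remainders, so every valid mix yields
    a full block.
    """
    types = list(proportions)
    raw = {t: proportions[t] * n for t in types}
    counts = {t: int(math.floor(raw[t])) for t in types}
    short = n - sum(counts.values())
    if short < 0:  # cannot happen with non-negative proportions summing to 1
        raise InvalidConfigError("proportions over-allocate the block")
    by_remainder = sorted(types, key=lambda t: (-(raw[t] - counts[t]), t.value))
    for t in by_remainder[:short]:
        counts[t] += 1
    return counts


def _block_sequence(
    counts: Mapping[TrialType, int], rng: np.random.Generator
) -> list[TrialType]:
    """Random block order with no two adjacent STOP trials.

    Non-STOP trials are permuted, then STOP trials are inserted into distinct
    gaps between them, which makes adjacency impossible by construction.
    """
    n_stop = counts.get(TrialType.STOP, 0)
    others: list[TrialType] = []
    for t, c in counts.items():
        if t is not TrialType.STOP:
            others.extend([t] * c)
    others = [others[i] for i in rng.permutation(len(others))]
    if n_stop == 0:
        return others
    if n_stop > len(others) + 1:
        raise InvalidConfigError("too many STOP trials to avoid adjacency")
    gaps = np.sort(rng.choice(len(others) + 1, size=n_stop, replace=False))
    seq: list[TrialType] = []
    prev = 0
    for g in gaps:
        seq.extend(others[prev:g])
        seq.append(TrialType.STOP)
        prev = g
    seq.extend(others[prev:])
    return seq


def build_trial_sequence(config: TaskConfig, seed: int) -> list[TrialType]:
    """Trial-type sequence for all blocks of a session (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    return _build_trial_sequence(config, rng)


def _build_trial_sequence(config: TaskConfig, rng: np.random.Generator) -> list[TrialType]:
    counts = _allocate_block(config.proportions, config.trials_per_block)
    seq: list[TrialType] = []
    for _ in range(config.n_blocks):
        seq.extend(_block_sequence(counts, rng))
    return seq


def _exgauss(rng: np.random.Generator, params: RaceParams, size: int) -> np.ndarray:
    return (
        params.go_mu
        + params.go_sigma * rng.standard_normal(size)
        + params.go_tau * rng.standard_exponential(size)
    )


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by redrawing (exact; at the default
    stopping parameters negative draws are ~7 sigma out, so redraws are rare)."""
    out = rng.normal(mean, sd, size)
    while True:
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def simulate_stop_outcomes(
    params: RaceParams, ssd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean "responded" outcomes of ``n`` independent STOP trials at a
    fixed SSD (no staircase); the direct Monte-Carlo view of the race."""
    go = _exgauss(rng, params, n)
    stop = ssd + _trunc_normal(rng, params.ssrt_true, params.ssrt_sd, n)
    tf = rng.random(n) < params.p_trigger_failure
    return tf | (go < stop)


_TYPE_OFFSET_FIELDS = {
    TrialType.GO: None,
    TrialType.GO_FAST: "gf_offset",
    TrialType.GO_CERTAIN: "gc_offset",
}


def simulate_session(
    config: TaskConfig,
    params: RaceParams,
    seed: int,
    subject_id: str = "S01",
    condition: str = "OFF",
) -> Session:
    """Simulate one session under the race model and the SSD staircase.

    The SSD starts at ``config.initial_ssd``; after every STOP trial it moves
    up ``staircase_step`` on a successful inhibition and down on a failure,
    clipped to ``ssd_bounds``.  Each later block restarts from the mean SSD of
    the last four STOP trials of the previous block.  Go-family responses
    slower than the 1200 ms deadline are recorded as omissions (task errors).
    """
    rng = np.random.default_rng(seed)
    seq = _build_trial_sequence(config, rng)
    n = len(seq)

    go_finish = _exgauss(rng, params, n)
    stop_lat = _trunc_normal(rng, params.ssrt_true, params.ssrt_sd, n)
    trig_fail = rng.random(n) < params.p_trigger_failure

    lo, hi = config.ssd_bounds
    ssd = float(np.clip(config.initial_ssd, lo, hi))
    trials: list[TrialRecord] = []
    block_ssds: list[float] = []

    for i, ttype in enumerate(seq):
        block = i // config.trials_per_block
        if i > 0 and i % config.trials_per_block == 0:
            # new block: restart from the last block's final staircase level
            if block_ssds:
                ssd = float(np.clip(np.mean(block_ssds[-4:]), lo, hi))
            block_ssds = []
        if ttype is TrialType.STOP:
            stop_finish = ssd + stop_lat[i]
            responded = bool(trig_fail[i] or go_finish[i] < stop_finish)
            trials.append(
                TrialRecord(
                    index=i,
                    block=block,
                    trial_type=ttype,
                    ssd=ssd,
                    responded=responded,
                    rt=float(go_finish[i]) if responded else None,
                    stop_success=not responded,
                )
            )
            block_ssds.append(ssd)
            step = config.staircase_step if not responded else -config.staircase_step
            ssd = float(np.clip(ssd + step, lo, hi))
        else:
            offset_field = _TYPE_OFFSET_FIELDS[ttype]
            rt = go_finish[i] + (getattr(params, offset_field) if offset_field else 0.0)
            responded = rt <= RESPONSE_DEADLINE_MS
            trials.append(
                TrialRecord(
                    index=i,
                    block=block,
                    trial_type=ttype,
                    responded=bool(responded),
                    rt=float(rt) if responded else None,
                )
            )
    return Session(subject_id, condition, trials, config, params)


#: Coefficient of variation of the between-subject lognormal jitter applied
#: to go_mu and ssrt_true when simulating a cohort.
SUBJECT_JITTER_CV = 0.10


def simulate_cohort(
    n_subjects: int,
    config: TaskConfig,
    off_params: RaceParams,
    on_effects: Mapping[str, float],
    seed: int,
) -> list[tuple[Session, Session]]:
    """Paired ON/OFF sessions for a cohort of heterogeneous subjects.

    Subject-level go_mu and ssrt_true are jittered lognormally (10% CV)
    around ``off_params``.  The ON condition speeds go responses by
    ``on_effects['rt_shift']`` ms and lengthens the stopping latency by
    ``on_effects['ssrt_shift']`` ms, the direction of the stimulation effect.
    Returns one ``(session_on, session_off)`` pair per subject.
    """
    if n_subjects < 2:
        raise InvalidConfigError("a cohort needs at least 2 subjects")
    rt_shift = float(on_effects.get("rt_shift", 0.0))
    ssrt_shift = float(on_effects.get("ssrt_shift", 0.0))
    rng = np.random.default_rng(seed)
    log_sd = math.sqrt(math.log(1.0 + SUBJECT_JITTER_CV**2))
    pairs: list[tuple[Session, Session]] = []
    for s in range(n_subjects):
        jit_mu, jit_ssrt = np.exp(rng.normal(-0.5 * log_sd**2, log_sd, 2))
        subj_off = replace(
            off_params,
            go_mu=off_params.go_mu * jit_mu,
            ssrt_true=off_params.ssrt_true * jit_ssrt,
        )
        subj_on = replace(
            subj_off,
            go_mu=subj_off.go_mu - rt_shift,
            ssrt_true=subj_off.ssrt_true + ssrt_shift,
        )
        sid = f"S{s + 1:02d}"
        seed_on, seed_off = rng.integers(0, 2**31, 2)
        pairs.append(
            (
                simulate_session(config, subj_on, int(seed_on), sid, "ON"),
                simulate_session(config, subj_off, int(seed_off), sid, "OFF"),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# EEG synthesis


@dataclass(frozen=True)
class ErpComponent:
    """One evoked component: a Gaussian bump in time projected through a
    fixed scalp topography.  ``half_width`` is the half width at half
    maximum of the bump (ms); ``alignment`` names the cue the component is
    locked to."""

    name: str
    latency: float
    half_width: float
    amplitude: float
    topography: np.ndarray
    alignment: str  # "GO_CUE" or "STOP_CUE"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise InvalidConfigError("component half_width must be positive")
        if self.alignment not in ("GO_CUE", "STOP_CUE"):
            raise InvalidConfigError(f"unknown alignment {self.alignment!r}")
        object.__setattr__(
            self, "topography", np.asarray(self.topography, dtype=float)
        )


@dataclass(frozen=True)
class ErpTemplates:
    """Generative ERP model for a session.

    ``condition_effects`` maps condition -> component name -> (amplitude
    factor, latency shift ms) and carries the stimulation effects (e.g. the
    ON-condition P300 delay).  ``us_attenuation`` scales the stop-locked
    N200/P300 on unsuccessful stops, where the inhibition process lost the
    race."""

    components: tuple[ErpComponent, ...]
    channel_labels: tuple[str, ...]
    srate: float = 250.0
    window: tuple[float, float] = (-200.0, 500.0)
    condition_effects: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    us_attenuation: float = 0.6

    def __post_init__(self) -> None:
        if self.srate <= 0:
            raise InvalidConfigError("srate must be positive")
        n = len(self.channel_labels)
        for c in self.components:
            if c.topography.shape != (n,):
                raise InvalidConfigError(
                    f"topography of {c.name} has {c.topography.shape[0]} entries, "
                    f"montage has {n} channels"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class EEGEpochs:
    """trials x channels x samples tensor of epoched EEG (microvolts).

    ``time0`` is the sample index of the alignment cue; ``window`` the epoch
    extent in ms relative to it (endpoints inclusive).  ``ground_truth``
    holds, when the epochs are synthetic, the noiseless inhibition-related
    (stop-locked) part of each epoch for recovery tests.
    """

    data: np.ndarray
    srate: float
    channel_labels: tuple[str, ...]
    window: tuple[float, float]
    alignment: str  # "GO_CUE" or "STOP_CUE"
    trial_meta: list[TrialRecord]
    ground_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        n_expected = round((self.window[1] - self.window[0]) / 1000.0 * self.srate) + 1
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"window {self.window} at {self.srate} Hz implies {n_expected} "
                f"samples, data has {self.data.shape[2]}"
            )
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length must equal trial count")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length must equal channel count")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to the alignment cue."""
        return self.window[0] + np.arange(self.data.shape[2]) * 1000.0 / self.srate

    @property
    def time0(self) -> int:
        return int(round(-self.window[0] / 1000.0 * self.srate))

    def channel(self, label: str) -> int:
        return self.channel_labels.index(label)


_1010_CORE = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
]


@lru_cache(maxsize=4)
def _montage_positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in flux across MNE releases; the positions are stable
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    return {
        name: pos
        for name, pos in montage.get_positions()["ch_pos"].items()
        if np.isfinite(pos).all()
    }


@lru_cache(maxsize=4)
def default_channel_labels(n_channels: int = 96) -> tuple[str, ...]:
    """A deterministic ``n_channels``-electrode montage: the 10-10 core
    (which includes F4) padded with further 10-5 positions from the standard
    montage."""
    positions = _montage_positions()
    labels = [name for name in _1010_CORE if name in positions]
    if len(labels) < n_channels:
        extras = [n for n in positions if n not in set(labels)]
        labels.extend(sorted(extras)[: n_channels - len(labels)])
    return tuple(labels[:n_channels])


def _spatial_gaussian(
    labels: Sequence[str], center: str, width_m: float = 0.055
) -> np.ndarray:
    """Scalp weight vector: Gaussian in 3-D electrode distance from a center
    electrode (unit peak)."""
    positions = _montage_positions()
    c = positions[center]
    w = np.array(
        [math.exp(-float(np.sum((positions[l] - c) ** 2)) / (2 * width_m**2)) for l in labels]
    )
    return w


def default_templates(
    n_channels: int = 96,
    srate: float = 250.0,
    p300_on_amp_factor: float = 0.82,
    p300_on_latency_shift: float = 17.0,
    n200_on_amp_factor: float = 0.88,
) -> ErpTemplates:
    """Default generative ERP model.

    Stop-locked N100 (fronto-central, -4 uV @ 100 ms), N200 (right-frontal,
    -6 uV @ 200 ms) and P300 (centro-parietal, +8 uV @ 300 ms), plus a
    go-locked motor component over the left motor cortex (right-hand
    responses).  The default ON-condition effects reduce N200/P300 amplitude
    and delay the P300, mirroring the direction of the stimulation effects.
    """
    labels = default_channel_labels(n_channels)
    comps = (
        ErpComponent("N100", 100.0, 25.0, -4.0, _spatial_gaussian(labels, "FCz"), "STOP_CUE"),
        ErpComponent("N200", 200.0, 30.0, -6.0, _spatial_gaussian(labels, "F4", 0.065), "STOP_CUE"),
        ErpComponent("P300", 300.0, 45.0, 8.0, _spatial_gaussian(labels, "CPz", 0.075), "STOP_CUE"),
        ErpComponent("GO_MOTOR", 300.0, 60.0, 5.0, _spatial_gaussian(labels, "C3"), "GO_CUE"),
    )
    effects = {
        "ON": {
            "N200": (n200_on_amp_factor, 0.0),
            "P300": (p300_on_amp_factor, p300_on_latency_shift),
        }
    }
    return ErpTemplates(
        components=comps,
        channel_labels=labels,
        srate=srate,
        condition_effects=effects,
    )


def _bump(times: np.ndarray, latency: float, half_width: float) -> np.ndarray:
    # half_width is HWHM; convert to the Gaussian sigma
    sigma = half_width / math.sqrt(2.0 * math.log(2.0))
    return np.exp(-((times - latency) ** 2) / (2.0 * sigma**2))


def _component_effect(
    templates: ErpTemplates, condition: str, name: str
) -> tuple[float, float]:
    return tuple(templates.condition_effects.get(condition, {}).get(name, (1.0, 0.0)))


def synthesize_eeg(
    session: Session,
    templates: ErpTemplates,
    noise_sd: float,
    seed: int,
) -> dict[str, EEGEpochs]:
    """Synthesize epoched EEG for a session.

    Returns ``{"GO": epochs, "STOP": epochs}``: go-cue-locked epochs for GO
    trials and stop-cue-locked epochs for STOP trials, both over the
    (-200, +500) ms window.  In stop epochs the go-locked motor component
    appears shifted to ``latency - SSD`` (the overlapping go process), the
    stop-locked N100 is always present, and N200/P300 appear at full
    amplitude on successful stops but attenuated on unsuccessful ones.  The
    stop-locked (inhibition) part of each stop epoch, noiseless, is stored in
    ``ground_truth``; for go epochs the full noiseless epoch is stored.
    """
    if templates.n_channels < 1:
        raise InvalidConfigError("montage must contain at least one channel")
    rng = np.random.default_rng(seed)
    tmin, tmax = templates.window
    n_samp = round((tmax - tmin) / 1000.0 * templates.srate) + 1
    times = tmin + np.arange(n_samp) * 1000.0 / templates.srate
    cond = session.condition

    def render(comp: ErpComponent, latency_offset: float, scale: float) -> np.ndarray:
        amp_f, lat_shift = _component_effect(templates, cond, comp.name)
        tc = _bump(times, comp.latency + lat_shift + latency_offset, comp.half_width)
        return (comp.amplitude * amp_f * scale) * np.outer(comp.topography, tc)

    out: dict[str, EEGEpochs] = {}

    go_trials = session.of_type(TrialType.GO)
    go_clean = np.zeros((len(go_trials), templates.n_channels, n_samp))
    for i, _tr in enumerate(go_trials):
        for comp in templates.components:
            if comp.alignment == "GO_CUE":
                go_clean[i] += render(comp, 0.0, 1.0)
    go_data = go_clean + rng.normal(0.0, noise_sd, go_clean.shape) if noise_sd > 0 else go_clean.copy()
    out["GO"] = EEGEpochs(
        go_data, templates.srate, templates.channel_labels, templates.window,
        "GO_CUE", go_trials, ground_truth=go_clean,
    )

    stop_trials = session.of_type(TrialType.STOP)
    stop_clean = np.zeros((len(stop_trials), templates.n_channels, n_samp))
    inhibition = np.zeros_like(stop_clean)
    for i, tr in enumerate(stop_trials):
        atten = 1.0 if tr.stop_success else templates.us_attenuation
        for comp in templates.components:
            if comp.alignment == "GO_CUE":
                # go-locked activity, seen at latency - SSD in stop-cue time
                stop_clean[i] += render(comp, -float(tr.ssd), 1.0)
            else:
                scale = atten if comp.name in ("N200", "P300") else 1.0
                c = render(comp, 0.0, scale)
                stop_clean[i] += c
                inhibition[i] += c
    stop_data = (
        stop_clean + rng.normal(0.0, noise_sd, stop_clean.shape)
        if noise_sd > 0
        else stop_clean.copy()
    )
    out["STOP"] = EEGEpochs(
        stop_data, templates.srate, templates.channel_labels, templates.window,
        "STOP_CUE", stop_trials, ground_truth=inhibition,
    )
    return out
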