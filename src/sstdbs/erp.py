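"""Inhibition ERP extraction.

Epochs -> ERPs: zero-phase band-pass filtering and decimation, common-average
referenced baseline-corrected trial averages, the race-model Go-process
correction that isolates stop-locked (inhibition) activity in successful and
unsuccessful stop trials, the global field power as the per-sample sum of
absolute deviations from the scalp mean, and windowed peak measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .behavior import summarize_session
from .task_sim import EEGEpochs, Session, TrialType

__all__ = [
    "ERP",
    "GFPSeries",
    "PeakMeasure",
    "DEFAULT_PEAK_WINDOWS",
    "preprocess",
    "average_erp",
    "go_correction",
    "compute_gfp",
    "measure_peaks",
]

logger = logging.getLogger(__name__)

#: Component search windows (ms), centred on the nominal latencies.
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "N100": (75.0, 125.0),
    "N200": (175.0, 225.0),
    "P300": (275.0, 325.0),
}

DEFAULT_BASELINE: tuple[float, float] = (-150.0, -50.0)


@dataclass
class ERP:
    """Trial-averaged, common-average-referenced epoch (channels x samples,
    microvolts)."""

    data: np.ndarray
    srate: float
    window: tuple[float, float]
    alignment: str
    n_trials: int
    channel_labels: tuple[str, ...]
    condition: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) * 1000.0 / self.srate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass
class GFPSeries:
    """Global field power: per sample, the sum over electrodes of the
    absolute deviation from the scalp-wide mean.  Non-negative by
    construction and invariant to channel-constant offsets."""

    values: np.ndarray
    srate: float
    window: tuple[float, float]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.values.size) * 1000.0 / self.srate


@dataclass
class PeakMeasure:
    """A detected peak: largest local extremum of the requested polarity in
    the search window; ``at_edge`` flags a fallback window-edge maximum when
    no interior local extremum exists."""

    component: str
    latency: float
    amplitude: float
    window: tuple[float, float]
    at_edge: bool = False


def preprocess(
    epochs: EEGEpochs,
    band: tuple[float | None, float | None] = (1.0, 45.0),
    target_srate: float = 250.0,
) -> EEGEpochs:
    """Zero-phase Butterworth filtering followed by polyphase resampling.

    ``band`` edges may be ``None`` to request a pure low- or high-pass.
    Filtering is forward-backward (no phase distortion); resampling uses an
    anti-aliasing FIR.  Window metadata is recomputed from the resampled
    sample grid.
    """
    low, high = band
    nyq = epochs.srate / 2.0
    for edge in (low, high):
        if edge is not None and not 0.0 < edge < nyq:
            raise ValueError(f"band edge {edge} Hz outside (0, Nyquist={nyq}) Hz")
    if low is not None and high is not None:
        sos = scipy.signal.butter(4, [low, high], btype="bandpass", fs=epochs.srate, output="sos")
    elif high is not None:
        sos = scipy.signal.butter(4, high, btype="lowpass", fs=epochs.srate, output="sos")
    elif low is not None:
        sos = scipy.signal.butter(4, low, btype="highpass", fs=epochs.srate, output="sos")
    else:
        raise ValueError("at least one band edge is required")
    data = scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1)

    if target_srate != epochs.srate:
        ratio = Fraction(target_srate / epochs.srate).limit_denominator(1000)
        up, down = ratio.numerator, ratio.denominator
        data = scipy.signal.resample_poly(data, up, down, axis=-1)
    n_new = data.shape[-1]
    tmin = epochs.window[0]
    tmax = tmin + (n_new - 1) * 1000.0 / target_srate
    return EEGEpochs(
        np.ascontiguousarray(data),
        target_srate,
        epochs.channel_labels,
        (tmin, tmax),
        epochs.alignment,
        epochs.trial_meta,
        ground_truth=None,
    )


def _car(data: np.ndarray) -> np.ndarray:
    """Common-average reference along the channel axis (axis 0 of a 2-D
    channel x sample array)."""
    return data - data.mean(axis=0, keepdims=True)


def _baseline_indices(
    times: np.ndarray, baseline: tuple[float, float]
) -> np.ndarray:
    idx = np.flatnonzero((times >= baseline[0]) & (times <= baseline[1]))
    if idx.size == 0:
        raise ValueError(f"baseline {baseline} ms outside the epoch window")
    return idx


def _reference_and_baseline(
    mean: np.ndarray, times: np.ndarray, baseline: tuple[float, float]
) -> np.ndarray:
    ref = _car(mean)
    idx = _baseline_indices(times, baseline)
    return ref - ref[:, idx].mean(axis=1, keepdims=True)


def average_erp(
    epochs: EEGEpochs,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    condition: str = "",
) -> ERP:
    """Trial average, common-average referenced, per-channel baseline
    subtracted.  After referencing, the mean across channels is zero at every
    sample, and baseline subtraction preserves that (channel baseline means
    of a referenced signal themselves average to zero)."""
    if epochs.data.shape[0] == 0:
        raise ValueError("cannot average an empty set of epochs")
    mean = epochs.data.mean(axis=0)
    data = _reference_and_baseline(mean, epochs.times, baseline)
    return ERP(
        data,
        epochs.srate,
        epochs.window,
        epochs.alignment,
        epochs.data.shape[0],
        epochs.channel_labels,
        condition,
    )


def _shift_samples(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift a channels x samples array left by ``shift`` samples (content at
    sample j of the output came from sample j+shift of the input), zero
    padding outside."""
    out = np.zeros_like(x)
    n = x.shape[-1]
    if shift >= n or shift <= -n:
        return out
    if shift >= 0:
        out[..., : n - shift] = x[..., shift:]
    else:
        out[..., -shift:] = x[..., : n + shift]
    return out


def go_correction(
    stop_epochs: EEGEpochs,
    go_epochs: EEGEpochs,
    session: Session,
    rt_tolerance: float = 50.0,
    ssrt: float | None = None,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
) -> dict[str, ERP]:
    """Remove overlapping Go-process activity from stop-trial epochs.

    The race model implies that every stop trial contains go-locked activity
    beginning at ``-SSD`` in stop-cue time.  For each unsuccessful stop (the
    go process won), the subtrahend is the average of go-trial epochs whose
    RT lies within ``rt_tolerance`` ms of that trial's response.  For each
    successful stop (the go process would have finished after SSD + SSRT),
    the subtrahend averages the go trials with RT > SSD + SSRT — those whose
    go process would have escaped inhibition.  Both subtrahends are shifted
    by the trial's SSD (rounded to the nearest sample) into stop-cue time
    before subtraction.  Stop trials with no matching go trials fall back to
    the grand go average (logged).  Corrected trials are averaged per class
    into common-average-referenced, baseline-corrected ERPs.
    """
    if stop_epochs.alignment != "STOP_CUE" or go_epochs.alignment != "GO_CUE":
        raise ValueError("expected stop epochs locked to STOP_CUE and go epochs to GO_CUE")
    if stop_epochs.srate != go_epochs.srate:
        raise ValueError("stop and go epochs must share a sampling rate")
    if ssrt is None:
        summ = summarize_session(session)
        ssrt = summ.ssrt if summ.ssrt is not None else 0.0

    go_rts = np.array(
        [t.rt if t.rt is not None else np.nan for t in go_epochs.trial_meta]
    )
    valid_go = np.isfinite(go_rts)
    grand_avg = go_epochs.data[valid_go].mean(axis=0) if valid_go.any() else np.zeros(
        go_epochs.data.shape[1:]
    )

    corrected = {"SS": [], "US": []}
    ms_per_sample = 1000.0 / stop_epochs.srate
    for i, tr in enumerate(stop_epochs.trial_meta):
        if tr.trial_type is not TrialType.STOP:
            raise ValueError("stop_epochs contain a non-STOP trial")
        shift = int(round(tr.ssd / ms_per_sample))
        if tr.stop_success:
            mask = valid_go & (go_rts > tr.ssd + ssrt)
            cls = "SS"
        else:
            mask = valid_go & (np.abs(go_rts - tr.rt) <= rt_tolerance)
            cls = "US"
        if mask.any():
            sub = go_epochs.data[mask].mean(axis=0)
        else:
            logger.warning(
                "stop trial %d (%s): no matching go trials, using grand go average",
                tr.index, cls,
            )
            sub = grand_avg
        corrected[cls].append(stop_epochs.data[i] - _shift_samples(sub, shift))

    out: dict[str, ERP] = {}
    for cls, key in (("SS", "erp_ss"), ("US", "erp_us")):
        trials = corrected[cls]
        if trials:
            mean = np.mean(trials, axis=0)
            data = _reference_and_baseline(mean, stop_epochs.times, baseline)
            n = len(trials)
        else:
            data = np.zeros(stop_epochs.data.shape[1:])
            n = 0
        out[key] = ERP(
            data, stop_epochs.srate, stop_epochs.window, "STOP_CUE",
            n, stop_epochs.channel_labels, session.condition,
        )
    return out


def compute_gfp(erp: ERP) -> GFPSeries:
    """GFP(t) = sum over channels of |x_c(t) - mean_c x_c(t)|."""
    if erp.data.shape[0] < 2:
        raise ValueError("GFP requires at least two channels")
    dev = erp.data - erp.data.mean(axis=0, keepdims=True)
    return GFPSeries(np.abs(dev).sum(axis=0), erp.srate, erp.window)


def measure_peaks(
    values: np.ndarray | GFPSeries,
    times: np.ndarray | None = None,
    windows: Mapping[str, tuple[float, float]] | None = None,
    polarities: Mapping[str, int] | None = None,
) -> list[PeakMeasure]:
    """Windowed peak amplitude and latency of a 1-D series.

    For each component the largest local extremum of the requested polarity
    (+1 maxima, -1 minima; GFP components are always positive) inside the
    window is returned; ties go to the earliest latency and plateaus to
    their first sample.  When the window holds no local extremum the window
    edge maximum is returned flagged ``at_edge``.
    """
    if isinstance(values, GFPSeries):
        times = values.times
        values = values.values
    if times is None:
        raise ValueError("times are required when values is a plain array")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if windows is None:
        windows = DEFAULT_PEAK_WINDOWS
    polarities = dict(polarities or {})

    results: list[PeakMeasure] = []
    for name, (t0, t1) in windows.items():
        if t0 < times[0] or t1 > times[-1]:
            raise ValueError(f"window {name} ({t0}, {t1}) ms outside the series extent")
        pol = polarities.get(name, -1 if name.startswith("N") else 1)
        s = pol * values
        in_win = np.flatnonzero((times >= t0) & (times <= t1))
        # local maxima of the signed series over the whole extent: strictly
        # above the previous sample, not below the next (plateau -> earliest)
        interior = np.arange(1, s.size - 1)
        is_peak = (s[interior] > s[interior - 1]) & (s[interior] >= s[interior + 1])
        peaks = interior[is_peak]
        peaks = peaks[np.isin(peaks, in_win)]
        if peaks.size:
            best = peaks[np.lexsort((times[peaks], -s[peaks]))][0]
            at_edge = False
        else:
            best = in_win[np.argmax(s[in_win])]
            at_edge = True
        results.append(
            PeakMeasure(name, float(times[best]), float(values[best]), (t0, t1), at_edge)
        )
    return results
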