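"""Action-potential feature extraction from current-clamp sweeps.

A sweep is one 500 ms current step (−500 to +500 pA in 100 pA increments in
the standard protocol).  Depolarizing sweeps are scanned for AP events —
(threshold, peak, afterhyperpolarization) triplets — from which the summary
features used to separate striatal cell classes are computed: half-height
width (HHW), interspike interval (ISI), instantaneous firing frequency
(IFF = 1000/ISI, Hz), and maximum firing frequency (MFF = max IFF).
Hyperpolarizing sweeps yield resting membrane potential and input resistance.

Conventions:

* AP threshold is the first sample whose dV/dt reaches the configured slope
  cut (default 20 mV/ms) on the rising approach to a peak.
* The AHP is the voltage minimum between a peak and the next AP threshold
  (or the step offset for the last event).
* HHW resamples the threshold→AHP window onto 1,000 evenly spaced points by
  linear interpolation and measures the time between the first rising and
  last falling crossing of the half-amplitude level.
* No liquid-junction-potential correction is applied anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DVDT_THRESHOLD_DEFAULT = 20.0  # mV/ms
HHW_INTERP_POINTS = 1000
HHW_CUT_DEFAULT = 0.8  # ms, midway between the SPN and FSI group means
IFF_CUT_DEFAULT = 50.0  # Hz, likewise
STEADY_STATE_CV_CUT = 0.25
RMP_WINDOW_MS = 50.0


class EphysError(ValueError):
    pass


class CellClass(enum.Enum):
    SPN = "SPN"
    FSI = "FSI"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class SweepRecording:
    """One current-clamp step sweep.  time in ms, voltage in mV, current in pA."""

    time: np.ndarray
    voltage: np.ndarray
    current_step: float
    step_window: tuple[float, float]  # (onset ms, offset ms)
    sweep_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltage", v)
        if t.shape != v.shape:
            raise EphysError("time and voltage must have equal lengths")
        if len(t) < 2:
            raise EphysError("sweep must contain at least two samples")
        dt = np.diff(t)
        if dt.min() <= 0 or np.ptp(dt) > 1e-9:
            raise EphysError("sampling interval must be constant and positive")
        onset, offset = self.step_window
        if not (t[0] <= onset < offset <= t[-1]):
            raise EphysError("step window must lie inside the trace")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class APEvent:
    threshold: tuple[float, float]  # (time ms, voltage mV)
    peak: tuple[float, float]
    ahp: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.threshold[0] < self.peak[0] < self.ahp[0]):
            raise EphysError("event times must be ordered threshold < peak < AHP")
        if not self.peak[1] > self.threshold[1]:
            raise EphysError("peak voltage must exceed threshold voltage")


@dataclass
class APFeatureSet:
    """Per-sweep (or per-cell) AP summary features.

    ISI-derived fields are ``None`` when fewer than two events are available
    (flagged, never silently zero).
    """

    hhw: np.ndarray | None = None  # ms, per event
    isi: np.ndarray | None = None  # ms, per consecutive pair
    iff: np.ndarray | None = None  # Hz
    mff: float | None = None  # Hz
    mean_iff: float | None = None  # Hz
    rmp: float | None = None  # mV
    input_resistance: float | None = None  # MΩ
    steady_state: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def mean_hhw(self) -> float | None:
        if self.hhw is None or len(self.hhw) == 0:
            return None
        return float(np.mean(self.hhw))


def detect_aps(s: SweepRecording, dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT) -> list[APEvent]:
    """Find ordered, non-overlapping AP events within the step window.

    An event opens at the first sample whose forward-difference dV/dt reaches
    *dvdt_threshold* and closes when the voltage falls back to the threshold
    voltage; further slope crossings inside an open event are ignored, so a
    waveform with two local maxima on one rise yields a single event whose
    peak is the global maximum.  A sweep with no APs returns an empty list.
    """
    t, v = s.time, s.voltage
    onset, offset = s.step_window
    i0 = int(np.searchsorted(t, onset))
    i1 = int(np.searchsorted(t, offset, side="right"))
    dvdt = np.diff(v) / s.dt  # forward difference; dvdt[i] is the slope leaving sample i

    rising = np.zeros(len(v), dtype=bool)
    rising[: len(dvdt)] = dvdt >= dvdt_threshold
    onsets = [
        i
        for i in range(i0, min(i1, len(v) - 1))
        if rising[i] and (i == i0 or not rising[i - 1])
    ]

    # pass 1: deduplicate onsets into event windows [thr_idx, end_idx]
    windows: list[tuple[int, int]] = []
    cursor = -1
    for i in onsets:
        if i <= cursor:
            continue
        vt = v[i]
        j = i + 1
        while j < i1 - 1 and v[j] > vt:
            j += 1
        if v[max(i + 1, i) : j + 1].max(initial=-np.inf) <= vt:
            continue  # slope artifact with no excursion above threshold
        windows.append((i, j))
        cursor = j

    # pass 2: peak inside each window, AHP between peak and the next threshold
    events: list[APEvent] = []
    for k, (i, j) in enumerate(windows):
        seg = slice(i, j + 1)
        peak_rel = int(np.argmax(v[seg]))
        p = i + peak_rel
        ahp_end = windows[k + 1][0] if k + 1 < len(windows) else i1 - 1
        if ahp_end <= p:
            continue  # truncated terminal event
        a = p + int(np.argmin(v[p : ahp_end + 1]))
        if a <= p:
            a = min(p + 1, len(v) - 1)
        events.append(
            APEvent(
                threshold=(float(t[i]), float(v[i])),
                peak=(float(t[p]), float(v[p])),
                ahp=(float(t[a]), float(v[a])),
            )
        )
    return events


def compute_hhw(s: SweepRecording, e: APEvent, n_interp: int = HHW_INTERP_POINTS) -> float:
    """Half-height width (ms) of one AP by the 1,000-point interpolation rule."""
    half = e.threshold[1] + 0.5 * (e.peak[1] - e.threshold[1])
    t0, t1 = e.threshold[0], e.ahp[0]
    tt = np.linspace(t0, t1, n_interp)
    yy = np.interp(tt, s.time, s.voltage)

    above = yy >= half
    if not above.any():
        raise EphysError("malformed event: trace never reaches the half level")
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    if last == len(above) - 1:
        raise EphysError("malformed event: trace never recrosses the half level before the AHP")

    def _cross(k0: int, k1: int) -> float:
        y0, y1 = yy[k0], yy[k1]
        if y1 == y0:
            return float(tt[k1])
        return float(tt[k0] + (half - y0) / (y1 - y0) * (tt[k1] - tt[k0]))

    t_rise = float(tt[0]) if first == 0 else _cross(first - 1, first)
    t_fall = _cross(last, last + 1)
    return t_fall - t_rise


def compute_train_features(events: Sequence[APEvent]) -> APFeatureSet:
    """ISI/IFF/MFF from consecutive AP threshold times."""
    fs = APFeatureSet()
    if len(events) < 2:
        fs.flags.append("too_few_events_for_isi")
        return fs
    thres = np.array([e.threshold[0] for e in events])
    fs.isi = np.diff(thres)
    fs.iff = 1000.0 / fs.isi
    fs.mff = float(fs.iff.max())
    fs.mean_iff = float(fs.iff.mean())
    return fs


def compute_passive(sweeps: Sequence[SweepRecording]) -> tuple[float, float]:
    """(RMP mV, input resistance MΩ) from subthreshold sweeps.

    RMP is the mean voltage over the 50 ms before step onset, averaged across
    sweeps.  Input resistance is the least-squares slope of steady-state ΔV
    (mean over the last 10 % of the step window, minus baseline) against
    injected current, converted from mV/pA (GΩ) to MΩ.
    """
    if not sweeps:
        raise EphysError("no sweeps provided")
    baselines, deltas, currents = [], [], []
    for s in sweeps:
        onset, offset = s.step_window
        pre = (s.time >= onset - RMP_WINDOW_MS) & (s.time < onset)
        if not pre.any():
            pre = s.time < onset
        if not pre.any():
            raise EphysError("no pre-step samples for RMP")
        base = float(s.voltage[pre].mean())
        tail_start = offset - 0.1 * (offset - onset)
        tail = (s.time >= tail_start) & (s.time <= offset)
        baselines.append(base)
        deltas.append(float(s.voltage[tail].mean()) - base)
        currents.append(s.current_step)
    rmp = float(np.mean(baselines))
    currents_arr = np.array(currents)
    if len(set(currents)) < 2:
        raise EphysError("input resistance needs at least two distinct current steps")
    slope = np.polyfit(currents_arr, np.array(deltas), 1)[0]  # mV/pA = GΩ
    return rmp, float(slope * 1000.0)


def steady_state_check(events: Sequence[APEvent], cv_cut: float = STEADY_STATE_CV_CUT) -> tuple[bool, str]:
    """True when the firing has settled: CV of the last half of ISIs < cv_cut."""
    if len(events) < 4:
        return False, "too few events"
    isi = np.diff([e.threshold[0] for e in events])
    tail = isi[len(isi) // 2 :]
    cv = float(tail.std(ddof=0) / tail.mean())
    return (cv < cv_cut), f"cv={cv:.4f}"


def classify_cell(
    f: APFeatureSet,
    hhw_cut: float = HHW_CUT_DEFAULT,
    iff_cut: float = IFF_CUT_DEFAULT,
) -> CellClass:
    """SPN vs FSI from mean HHW and mean IFF at steady state.

    FSIs fire brief, fast APs (short HHW, high IFF); SPNs the converse.  A
    cell that never reached steady state, or whose features disagree across
    the two axes, is AMBIGUOUS.
    """
    if not f.steady_state:
        return CellClass.AMBIGUOUS
    hhw, iff = f.mean_hhw, f.mean_iff
    if hhw is None or iff is None:
        return CellClass.AMBIGUOUS
    if hhw < hhw_cut and iff > iff_cut:
        return CellClass.FSI
    if hhw >= hhw_cut and iff <= iff_cut:
        return CellClass.SPN
    return CellClass.AMBIGUOUS


def extract_features(
    sweeps: Sequence[SweepRecording],
    dvdt_threshold: float = DVDT_THRESHOLD_DEFAULT,
    cv_cut: float = STEADY_STATE_CV_CUT,
) -> APFeatureSet:
    """Full per-cell feature extraction over a protocol's sweeps.

    Train features (mean over depolarizing sweeps with ≥2 APs), HHW over all
    events, passive properties from hyperpolarizing sweeps.
    """
    hhws: list[float] = []
    mean_iffs: list[float] = []
    mffs: list[float] = []
    steady_flags: list[bool] = []
    hyper = [s for s in sweeps if s.current_step < 0]
    for s in sweeps:
        if s.current_step <= 0:
            continue
        events = detect_aps(s, dvdt_threshold)
        for e in events:
            hhws.append(compute_hhw(s, e))
        train = compute_train_features(events)
        if train.mean_iff is not None:
            mean_iffs.append(train.mean_iff)
            mffs.append(train.mff)
        ok, _ = steady_state_check(events, cv_cut)
        if len(events) >= 4:
            steady_flags.append(ok)

    fs = APFeatureSet()
    if hhws:
        fs.hhw = np.array(hhws)
    if mean_iffs:
        fs.mean_iff = float(np.mean(mean_iffs))
        fs.mff = float(np.max(mffs))
    else:
        fs.flags.append("no_spiking_sweeps")
    fs.steady_state = bool(steady_flags) and any(steady_flags)
    if len(hyper) >= 2:
        try:
            fs.rmp, fs.input_resistance = compute_passive(hyper)
        except EphysError as err:
            fs.flags.append(f"passive_failed:{err}")
    else:
        fs.flags.append("too_few_hyperpolarizing_sweeps")
    return fs
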