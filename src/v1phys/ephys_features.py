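"""Passive-membrane and action-potential feature extraction.

Operates on :class:`SweepSet` objects: a family of current-clamp sweeps
sharing a time base, one sweep per injected current step.  The AP
threshold is defined as the membrane potential at which dV/dt first
reaches a critical rate (default 15.2 mV/ms) on the upstroke; the AP
half-width is the time spent above the voltage halfway between threshold
and peak, with sub-sample linear interpolation at both crossings.

Units: time in ms, voltage in mV, current in pA, rates in mV/ms
internally.  ``APFeatures.max_rate_rise``/``max_rate_fall`` are reported
in mV/s in the tidy feature table (documented assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SweepSet",
    "PassiveProperties",
    "APFeatures",
    "MalformedAPError",
    "NoAPError",
    "CRITICAL_DVDT",
    "compute_dvdt",
    "detect_aps",
    "ap_threshold",
    "ap_features",
    "passive_properties",
    "first_ap_features",
    "extract_cell_features",
]

#: Critical rate of membrane-potential change defining the AP threshold (mV/ms).
CRITICAL_DVDT = 15.2


class MalformedAPError(ValueError):
    """Raised when a detected AP has no dV/dt threshold crossing before its peak."""


class NoAPError(ValueError):
    """Raised when a protocol contains no action potential at all."""


@dataclass
class SweepSet:
    """A current-clamp step protocol: one voltage sweep per current step.

    Attributes
    ----------
    time_ms : (n,) array, uniform sample times shared by all sweeps.
    voltage_mV : (n_sweeps, n) array.
    current_pA : (n_sweeps,) injected current per sweep.
    step_window_ms : (start, end) of the current step within the trace.
    sampling_rate_hz : nominal sampling rate.
    """

    time_ms: np.ndarray
    voltage_mV: np.ndarray
    current_pA: np.ndarray
    step_window_ms: tuple
    sampling_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mV = np.atleast_2d(np.asarray(self.voltage_mV, dtype=float))
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.validate()

    def validate(self):
        if self.voltage_mV.shape != (len(self.current_pA), len(self.time_ms)):
            raise ValueError(
                "voltage matrix shape %s inconsistent with %d sweeps x %d samples"
                % (self.voltage_mV.shape, len(self.current_pA), len(self.time_ms))
            )
        dt = np.diff(self.time_ms)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform time base")
        lo, hi = self.step_window_ms
        if not (self.time_ms[0] <= lo < hi <= self.time_ms[-1] + dt[0]):
            raise ValueError("step_window outside trace")
        if abs(1000.0 / dt[0] - self.sampling_rate_hz) > 0.01 * self.sampling_rate_hz:
            raise ValueError("sampling_rate inconsistent with time base")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def n_sweeps(self) -> int:
        return self.voltage_mV.shape[0]

    def sweep(self, i: int) -> np.ndarray:
        return self.voltage_mV[i]

    def order_by_current(self) -> np.ndarray:
        """Sweep indices sorted by increasing injected current."""
        return np.argsort(self.current_pA, kind="stable")


@dataclass
class PassiveProperties:
    input_resistance_MOhm: float
    capacitance_pF: Optional[float]
    time_constant_ms: Optional[float]
    voltage_sag_mV: float
    rebound_mV: float
    rheobase_pA: Optional[float]
    baseline_mV: float = np.nan
    diagnostics: dict = field(default_factory=dict)


@dataclass
class APFeatures:
    threshold_potential_mV: float
    amplitude_mV: float
    half_width_ms: float
    max_rate_rise_mV_per_s: float
    max_rate_fall_mV_per_s: Optional[float]
    total_rise_time_ms: float
    total_fall_time_ms: Optional[float]
    peak_time_ms: float
    threshold_time_ms: float
    peak_potential_mV: float
    source_sweep: int = -1


def compute_dvdt(voltage: np.ndarray, time_ms: np.ndarray) -> np.ndarray:
    """Central-difference dV/dt in mV/ms (one-sided at the ends)."""
    voltage = np.asarray(voltage, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if voltage.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    dt = np.diff(time_ms)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time base")
    return np.gradient(voltage, time_ms, axis=-1)


def detect_aps(
    voltage: np.ndarray,
    time_ms: np.ndarray,
    dvdt_threshold: float = CRITICAL_DVDT,
    peak_floor_mV: float = -10.0,
    search_window_ms: float = 5.0,
    refractory_ms: float = 2.0,
    dvdt: Optional[np.ndarray] = None,
) -> list:
    """Return sample indices of AP peaks in one sweep.

    A candidate is an upward crossing of ``dvdt_threshold`` by dV/dt; it is
    accepted when the local voltage maximum within ``search_window_ms``
    afterwards exceeds ``peak_floor_mV``.  Accepted peaks are separated by
    at least ``refractory_ms``.
    """
    voltage = np.asarray(voltage, dtype=float)
    if dvdt is None:
        dvdt = compute_dvdt(voltage, time_ms)
    dt = time_ms[1] - time_ms[0]
    w = max(1, int(round(search_window_ms / dt)))
    crossings = np.flatnonzero((dvdt[:-1] < dvdt_threshold) & (dvdt[1:] >= dvdt_threshold))
    peaks = []
    last_peak_t = -np.inf
    for c in crossings:
        hi = min(len(voltage), c + 1 + w)
        seg = voltage[c + 1 : hi]
        if len(seg) == 0:
            continue
        p = c + 1 + int(np.argmax(seg))
        if voltage[p] < peak_floor_mV:
            continue
        # must be a genuine local maximum, not a window-edge artefact
        if p + 1 < len(voltage) and voltage[p + 1] > voltage[p]:
            continue
        if time_ms[p] - last_peak_t < refractory_ms:
            continue
        if peaks and p == peaks[-1]:
            continue
        peaks.append(p)
        last_peak_t = time_ms[p]
    return peaks


def ap_threshold(
    voltage: np.ndarray,
    time_ms: np.ndarray,
    peak_index: int,
    dvdt_threshold: float = CRITICAL_DVDT,
    max_lookback_ms: float = 10.0,
    dvdt: Optional[np.ndarray] = None,
) -> tuple:
    """Threshold (voltage, time) of the AP ending at ``peak_index``.

    Scans backward from the point of maximal dV/dt preceding the peak and
    finds the last sample at which dV/dt is still below the critical rate;
    voltage and time are linearly interpolated at the exact crossing.
    (Scanning from the peak itself would stop inside the rounded peak,
    where dV/dt also dips below the critical rate.)
    """
    voltage = np.asarray(voltage, dtype=float)
    if dvdt is None:
        dvdt = compute_dvdt(voltage, time_ms)
    dt = time_ms[1] - time_ms[0]
    lo = max(0, peak_index - int(round(max_lookback_ms / dt)))
    if peak_index <= lo:
        raise MalformedAPError("peak at trace start")
    upstroke = lo + int(np.argmax(dvdt[lo : peak_index + 1]))
    if dvdt[upstroke] < dvdt_threshold:
        raise MalformedAPError("dV/dt never reaches %.3g mV/ms before peak" % dvdt_threshold)
    i = upstroke
    while i > lo and dvdt[i] >= dvdt_threshold:
        i -= 1
    if dvdt[i] >= dvdt_threshold or dvdt[i + 1] < dvdt_threshold or i + 1 > peak_index:
        raise MalformedAPError("dV/dt never crosses %.3g mV/ms before peak" % dvdt_threshold)
    # interpolate the crossing between samples i and i+1
    d0, d1 = dvdt[i], dvdt[i + 1]
    frac = 0.0 if d1 == d0 else (dvdt_threshold - d0) / (d1 - d0)
    v = voltage[i] + frac * (voltage[i + 1] - voltage[i])
    t = time_ms[i] + frac * dt
    return float(v), float(t)


def _cross_time(time_ms, voltage, i, level):
    """Linear-interpolated time at which voltage crosses ``level`` between i and i+1."""
    v0, v1 = voltage[i], voltage[i + 1]
    if v1 == v0:
        return float(time_ms[i])
    frac = (level - v0) / (v1 - v0)
    return float(time_ms[i] + frac * (time_ms[i + 1] - time_ms[i]))


def ap_features(
    voltage: np.ndarray,
    time_ms: np.ndarray,
    peak_index: int,
    dvdt_threshold: float = CRITICAL_DVDT,
    source_sweep: int = -1,
    search_end_ms: Optional[float] = None,
    dvdt: Optional[np.ndarray] = None,
) -> APFeatures:
    """Waveform features of one AP.

    ``total_fall_time`` is the time from the peak until the voltage first
    returns to the threshold potential; if the voltage never returns within
    the sweep (or ``search_end_ms``), it is recorded as missing (None) and
    the maximum rate of fall is measured over the available falling segment.
    """
    voltage = np.asarray(voltage, dtype=float)
    if dvdt is None:
        dvdt = compute_dvdt(voltage, time_ms)
    v_thr, t_thr = ap_threshold(voltage, time_ms, peak_index, dvdt_threshold, dvdt=dvdt)
    v_peak = float(voltage[peak_index])
    t_peak = float(time_ms[peak_index])
    amplitude = v_peak - v_thr
    if amplitude <= 0:
        raise MalformedAPError("non-positive amplitude")
    v_half = v_thr + amplitude / 2.0

    end = len(voltage)
    if search_end_ms is not None:
        end = min(end, int(np.searchsorted(time_ms, search_end_ms)))

    # rising half-height crossing: last upward crossing before the peak
    pre = voltage[: peak_index + 1]
    up = np.flatnonzero((pre[:-1] < v_half) & (pre[1:] >= v_half))
    if len(up) == 0:
        raise MalformedAPError("no rising half-height crossing")
    t_half_up = _cross_time(time_ms, voltage, up[-1], v_half)

    # falling half-height crossing: first downward crossing after the peak
    post = voltage[peak_index:end]
    down = np.flatnonzero((post[:-1] >= v_half) & (post[1:] < v_half))
    if len(down) == 0:
        raise MalformedAPError("no falling half-height crossing")
    j = peak_index + down[0]
    t_half_down = _cross_time(time_ms, voltage, j, v_half)
    half_width = t_half_down - t_half_up

    # return to threshold potential
    ret = np.flatnonzero((post[:-1] > v_thr) & (post[1:] <= v_thr))
    if len(ret) > 0:
        k = peak_index + ret[0]
        t_return = _cross_time(time_ms, voltage, k, v_thr)
        total_fall = t_return - t_peak
        fall_seg_end = k + 1
    else:
        total_fall = None
        fall_seg_end = end

    i_thr = int(np.searchsorted(time_ms, t_thr))
    seg = dvdt[max(i_thr, 0) : fall_seg_end + 1]
    max_rise = float(np.max(seg)) if len(seg) else np.nan
    max_fall = float(-np.min(seg)) if len(seg) else np.nan

    return APFeatures(
        threshold_potential_mV=v_thr,
        amplitude_mV=amplitude,
        half_width_ms=half_width,
        max_rate_rise_mV_per_s=max_rise * 1000.0,
        max_rate_fall_mV_per_s=None if total_fall is None and len(seg) == 0 else max_fall * 1000.0,
        total_rise_time_ms=t_peak - t_thr,
        total_fall_time_ms=total_fall,
        peak_time_ms=t_peak,
        threshold_time_ms=t_thr,
        peak_potential_mV=v_peak,
        source_sweep=source_sweep,
    )


def _exp_onset(t, v_ss, dv, tau):
    return v_ss - dv * np.exp(-t / tau)


def passive_properties(
    sweeps: SweepSet,
    passive_current_pA: float = -50.0,
    steady_fraction: float = 0.25,
    detect_kwargs: Optional[dict] = None,
) -> PassiveProperties:
    """Passive membrane properties from the hyperpolarizing step sweep.

    R_in from the steady-state deflection (last ``steady_fraction`` of the
    step), tau from a single-exponential fit to the onset transient,
    capacitance = tau / R_in.  Voltage sag and rebound are reported as
    positive magnitudes.  Rheobase is the smallest current step whose sweep
    contains at least one detected AP.
    """
    detect_kwargs = detect_kwargs or {}
    idx = np.flatnonzero(np.isclose(sweeps.current_pA, passive_current_pA, atol=0.5))
    if len(idx) == 0:
        raise ValueError("no %.4g pA sweep in protocol" % passive_current_pA)
    i = int(idx[0])
    v = sweeps.sweep(i)
    t = sweeps.time_ms
    lo, hi = sweeps.step_window_ms
    in_step = (t >= lo) & (t < hi)
    pre = t < lo
    post = t >= hi
    if not pre.any():
        raise ValueError("no pre-step baseline samples")
    v_base = float(np.mean(v[pre]))
    step_t = t[in_step]
    step_v = v[in_step]
    n_ss = max(1, int(round(steady_fraction * len(step_v))))
    v_steady = float(np.mean(step_v[-n_ss:]))
    r_in = (v_steady - v_base) / passive_current_pA * 1000.0  # mV/pA -> MOhm

    tau = cap = None
    diagnostics = {}
    try:
        trel = step_t - step_t[0]
        p0 = (v_steady, v_steady - v_base, max(1.0, 0.2 * (hi - lo)))
        popt, _ = curve_fit(_exp_onset, trel, step_v, p0=p0, maxfev=10000)
        tau = float(abs(popt[2]))
        cap = tau / r_in * 1000.0  # ms/MOhm -> pF
    except Exception as exc:  # fit failure -> missing tau/cap with diagnostic
        diagnostics["tau_fit_error"] = repr(exc)

    # sag: transient overshoot beyond steady state, positive magnitude
    if v_steady < v_base:  # hyperpolarizing step
        sag = max(0.0, v_steady - float(np.min(step_v)))
    else:
        sag = max(0.0, float(np.max(step_v)) - v_steady)
    # rebound: post-step excursion past baseline, positive magnitude
    if post.any():
        if v_steady < v_base:
            rebound = max(0.0, float(np.max(v[post])) - v_base)
        else:
            rebound = max(0.0, v_base - float(np.min(v[post])))
    else:
        rebound = 0.0

    rheobase = None
    for j in sweeps.order_by_current():
        if sweeps.current_pA[j] <= 0:
            continue
        peaks = detect_aps(sweeps.sweep(j), t, **detect_kwargs)
        if peaks:
            rheobase = float(sweeps.current_pA[j])
            break

    return PassiveProperties(
        input_resistance_MOhm=r_in,
        capacitance_pF=cap,
        time_constant_ms=tau,
        voltage_sag_mV=sag,
        rebound_mV=rebound,
        rheobase_pA=rheobase,
        baseline_mV=v_base,
        diagnostics=diagnostics,
    )


def first_ap_features(sweeps: SweepSet, detect_kwargs: Optional[dict] = None, **feature_kwargs) -> APFeatures:
    """Features of the chronologically first AP, sweeps ordered by increasing current."""
    detect_kwargs = detect_kwargs or {}
    for j in sweeps.order_by_current():
        peaks = detect_aps(sweeps.sweep(j), sweeps.time_ms, **detect_kwargs)
        if peaks:
            return ap_features(
                sweeps.sweep(j), sweeps.time_ms, peaks[0], source_sweep=int(j), **feature_kwargs
            )
    raise NoAPError("no AP fired anywhere in the protocol (no-AP cell)")


def extract_cell_features(sweeps: SweepSet, cell_id: str = "cell", **kwargs) -> dict:
    """One tidy row of per-cell features (Table-1 style column vocabulary)."""
    passive = passive_properties(sweeps, detect_kwargs=kwargs.get("detect_kwargs"))
    row = {
        "cell_id": cell_id,
        "input_resistance_MOhm": passive.input_resistance_MOhm,
        "capacitance_pF": passive.capacitance_pF,
        "time_constant_ms": passive.time_constant_ms,
        "voltage_sag_mV": passive.voltage_sag_mV,
        "rebound_mV": passive.rebound_mV,
        "rheobase_pA": passive.rheobase_pA,
    }
    try:
        ap = first_ap_features(sweeps, detect_kwargs=kwargs.get("detect_kwargs"))
        row.update(
            {
                "ap_threshold_mV": ap.threshold_potential_mV,
                "ap_amplitude_mV": ap.amplitude_mV,
                "ap_half_width_ms": ap.half_width_ms,
                "ap_max_rate_rise_mV_per_s": ap.max_rate_rise_mV_per_s,
                "ap_max_rate_fall_mV_per_s": ap.max_rate_fall_mV_per_s,
                "ap_total_rise_time_ms": ap.total_rise_time_ms,
                "ap_total_fall_time_ms": ap.total_fall_time_ms,
            }
        )
    except NoAPError:
        for k in (
            "ap_threshold_mV",
            "ap_amplitude_mV",
            "ap_half_width_ms",
            "ap_max_rate_rise_mV_per_s",
            "ap_max_rate_fall_mV_per_s",
            "ap_total_rise_time_ms",
            "ap_total_fall_time_ms",
        ):
            row[k] = None
    return row
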