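"""Current-clamp step-protocol simulator with closed-form AP waveforms.

The AP template is piecewise analytic so that every extracted feature has
an exact expected value:

* an exponentially accelerating foot whose dV/dt approaches the critical
  rate from below,
* a short zone around the threshold where dV/dt is *linear in time* and
  crosses the critical rate exactly at the configured threshold voltage
  (linear interpolation of a sampled central-difference derivative is then
  exact, so the extractor recovers the threshold to well under 0.1 mV),
* a fast exponential acceleration to the maximal rate of rise, a linear
  upstroke, a parabolic (rounded) peak, a linear downstroke, and an
  exponential relaxation back to the pre-spike plateau.

Geometry is solved so that the full width at half height equals
``half_width_ms`` exactly, split ``rise_fraction`` : 1 - ``rise_fraction``
between the rising and falling sides.

Sub-rheobase sweeps follow the RC step response
``V(t) = V0 + I R (1 - exp(-t/tau))`` with ``tau = R C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .._utils import rng_from_seed
from ..ephys_features import CRITICAL_DVDT, SweepSet

__all__ = [
    "APTemplate",
    "EphysSimConfig",
    "EphysGroundTruth",
    "generate_current_clamp_recording",
]


@dataclass(frozen=True)
class APTemplate:
    """Piecewise-analytic AP waveform; all derived geometry is closed form.

    ``t = 0`` is the instant at which dV/dt first reaches ``critical_dvdt``
    (the threshold definition used by the extractor).
    """

    threshold_mV: float = -44.0
    amplitude_mV: float = 65.0  # threshold-to-peak
    half_width_ms: float = 0.978
    rise_fraction: float = 0.3  # share of the half-width on the rising side
    foot_depth_mV: float = 8.0  # plateau sits this far below threshold
    critical_dvdt: float = CRITICAL_DVDT  # mV/ms
    linear_zone_ms: float = 0.1  # half-width of the linear-dV/dt zone at threshold
    dvdt_slope: float = 25.0  # mV/ms^2 inside the linear zone
    accel_ms: float = 0.05  # duration of the post-zone acceleration to max rise rate
    cap_ms: float = 0.12  # minimum rounded-peak half-duration
    cap_fraction: float = 0.2

    # ---- derived geometry -------------------------------------------------
    def _geom(self) -> dict:
        vc, a, w = self.critical_dvdt, self.dvdt_slope, self.linear_zone_ms
        A, hw, f = self.amplitude_mV, self.half_width_ms, self.rise_fraction
        t_r, t_f = f * hw, (1.0 - f) * hw
        c = max(self.cap_ms, self.cap_fraction * min(t_r, t_f))
        if c / 2 >= min(t_r, t_f):
            raise ValueError("rounded-peak duration exceeds a half-width side")
        s_r = A / (2.0 * (t_r - c / 2))
        s_f = A / (2.0 * (t_f - c / 2))
        v_lo, v_hi = vc - a * w, vc + a * w
        if v_lo <= 0.5:
            raise ValueError("linear-zone slope too steep (dV/dt would go negative)")
        if s_r <= v_hi * 1.05:
            raise ValueError("max rate of rise must exceed the critical rate zone")
        dV_B2 = vc * w + a * w * w / 2  # voltage gained over [0, w]
        k2 = math.log(s_r / v_hi) / self.accel_ms
        dV_C = (s_r - v_hi) / k2  # voltage gained during acceleration
        if dV_B2 + dV_C >= A / 2:
            raise ValueError("half-height crossing must fall on the linear upstroke")
        d_A = self.foot_depth_mV - (vc * w - a * w * w / 2)
        if d_A <= 0.5:
            raise ValueError("foot_depth too shallow for the linear zone")
        k = v_lo / d_A
        t_pk = w + self.accel_ms + (A - dV_B2 - dV_C) / s_r + c / 2
        t_ret = t_pk + A / s_f + c / 2
        tau_e = self.foot_depth_mV / s_f
        return dict(
            t_r=t_r, t_f=t_f, c=c, s_r=s_r, s_f=s_f, v_lo=v_lo, v_hi=v_hi,
            dV_B2=dV_B2, dV_C=dV_C, k=k, k2=k2, t_pk=t_pk, t_ret=t_ret,
            tau_e=tau_e, w=w, a=a,
            t_start=-(w + math.log(200.0) / k),  # support start (depth ~ d_A/200 left)
            t_end=t_ret + 10.0 * tau_e,
        )

    @property
    def plateau_mV(self) -> float:
        return self.threshold_mV - self.foot_depth_mV

    def expected_features(self) -> dict:
        """Closed-form values of every feature the extractor measures."""
        g = self._geom()
        return {
            "threshold_potential_mV": self.threshold_mV,
            "peak_potential_mV": self.threshold_mV + self.amplitude_mV,
            "amplitude_mV": self.amplitude_mV,
            "half_width_ms": self.half_width_ms,
            "total_rise_time_ms": g["t_pk"],
            "total_fall_time_ms": g["t_ret"] - g["t_pk"],
            "max_rate_rise_mV_per_ms": g["s_r"],
            "max_rate_fall_mV_per_ms": g["s_f"],
            "peak_time_ms": g["t_pk"],  # relative to threshold crossing
        }

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Absolute membrane potential at times ``t`` (ms, 0 = threshold crossing)."""
        g = self._geom()
        t = np.asarray(t, dtype=float)
        V = np.empty_like(t)
        vth, A = self.threshold_mV, self.amplitude_mV
        vpk = vth + A
        plat = self.plateau_mV
        vc, a, w = self.critical_dvdt, g["a"], g["w"]
        tC = w + self.accel_ms
        t_cap1 = g["t_pk"] - g["c"]
        t_cap2 = g["t_pk"] + g["c"]

        m = t < -w  # foot
        V[m] = plat + (g["v_lo"] / g["k"]) * np.exp(g["k"] * (t[m] + w))
        m = (t >= -w) & (t < w)  # linear-dV/dt zone: quadratic voltage
        V[m] = vth + vc * t[m] + a * t[m] ** 2 / 2
        m = (t >= w) & (t < tC)  # exponential acceleration to s_r
        V[m] = (vth + g["dV_B2"]) + (g["v_hi"] / g["k2"]) * (np.exp(g["k2"] * (t[m] - w)) - 1.0)
        m = (t >= tC) & (t < t_cap1)  # linear upstroke
        V[m] = (vth + g["dV_B2"] + g["dV_C"]) + g["s_r"] * (t[m] - tC)
        m = (t >= t_cap1) & (t < g["t_pk"])  # rising half of the rounded peak
        V[m] = vpk - g["s_r"] * (g["t_pk"] - t[m]) ** 2 / (2 * g["c"])
        m = (t >= g["t_pk"]) & (t < t_cap2)  # falling half of the rounded peak
        V[m] = vpk - g["s_f"] * (t[m] - g["t_pk"]) ** 2 / (2 * g["c"])
        m = (t >= t_cap2) & (t < g["t_ret"])  # linear downstroke
        V[m] = (vpk - g["s_f"] * g["c"] / 2) - g["s_f"] * (t[m] - t_cap2)
        m = t >= g["t_ret"]  # exponential relaxation to the plateau
        V[m] = plat + (vth - plat) * np.exp(-(t[m] - g["t_ret"]) / g["tau_e"])
        return V


@dataclass(frozen=True)
class EphysSimConfig:
    sampling_rate_hz: float = 50_000.0
    step_duration_ms: float = 200.0
    inter_step_interval_ms: float = 2000.0
    current_steps_pA: Tuple[float, ...] = tuple(range(-50, 651, 50))
    holding_potential_mV: float = -70.0
    membrane_R_MOhm: float = 100.0
    membrane_C_pF: float = 150.0
    ap_template: APTemplate = field(default_factory=APTemplate)
    rheobase_pA: float = 150.0
    noise_sd_mV: float = 0.0
    seed: int = 0
    # trace layout / spiking schedule (not part of the acquisition protocol)
    pre_ms: float = 100.0
    post_ms: float = 200.0
    sag_mV: float = 0.0
    rebound_mV: float = 0.0
    sag_peak_ms: float = 30.0
    first_spike_latency_ms: float = 30.0
    spike_interval_ms: float = 40.0
    extra_spike_per_pA: float = 100.0
    suprathreshold_tau_factor: float = 0.25

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration must be positive")
        if self.ap_template.half_width_ms <= 0:
            raise ValueError("half_width must be positive")
        steps = np.asarray(self.current_steps_pA, dtype=float)
        if len(steps) < 1 or np.any(np.diff(steps) <= 0):
            raise ValueError("current_steps must be strictly increasing")
        if not (steps.min() <= self.rheobase_pA <= steps.max()):
            raise ValueError("rheobase_pA outside the range of current_steps")
        if self.ap_template.plateau_mV <= self.holding_potential_mV + 1.0:
            raise ValueError("pre-spike plateau must sit above the holding potential")

    @property
    def tau_ms(self) -> float:
        return self.membrane_R_MOhm * self.membrane_C_pF / 1000.0


@dataclass
class EphysGroundTruth:
    template_features: dict
    membrane_R_MOhm: float
    membrane_C_pF: float
    tau_ms: float
    rheobase_pA: float  # smallest grid current at/above the configured rheobase
    spike_threshold_times_ms: Dict[int, List[float]]  # sweep index -> absolute times
    spike_peak_times_ms: Dict[int, List[float]]
    first_ap: Optional[tuple]  # (sweep index, threshold time, peak time)
    config: EphysSimConfig = None

    def to_dict(self) -> dict:
        return {
            "template_features": self.template_features,
            "membrane_R_MOhm": self.membrane_R_MOhm,
            "membrane_C_pF": self.membrane_C_pF,
            "tau_ms": self.tau_ms,
            "rheobase_pA": self.rheobase_pA,
            "spike_threshold_times_ms": {str(k): v for k, v in self.spike_threshold_times_ms.items()},
            "spike_peak_times_ms": {str(k): v for k, v in self.spike_peak_times_ms.items()},
            "first_ap": list(self.first_ap) if self.first_ap else None,
        }


def _alpha_bump(t: np.ndarray, peak_ms: float) -> np.ndarray:
    """Unit-peak alpha function, zero for t < 0."""
    x = np.clip(t / peak_ms, 0.0, None)
    return x * np.exp(1.0 - x)


def generate_current_clamp_recording(cfg: EphysSimConfig) -> tuple:
    """Simulate one cell's step protocol; returns (SweepSet, EphysGroundTruth)."""
    rng = rng_from_seed(cfg.seed)
    tpl = cfg.ap_template
    geom = tpl._geom()
    fs = cfg.sampling_rate_hz
    dt = 1000.0 / fs
    n = int(round((cfg.pre_ms + cfg.step_duration_ms + cfg.post_ms) / dt))
    t = np.arange(n) * dt
    t_on, t_off = cfg.pre_ms, cfg.pre_ms + cfg.step_duration_ms
    V0 = cfg.holding_potential_mV
    tau = cfg.tau_ms
    R = cfg.membrane_R_MOhm
    plat = tpl.plateau_mV

    # validity of the spike schedule: the underlying membrane must have settled
    # to within the template's truncation residual before the first foot begins
    tau_c = tau * cfg.suprathreshold_tau_factor
    resid = (geom["v_lo"] / geom["k"]) / 200.0
    settle = tau_c * math.log((plat - V0) / resid)
    foot_lead = -geom["t_start"]
    if cfg.first_spike_latency_ms - foot_lead < settle:
        raise ValueError(
            "first_spike_latency_ms too short: membrane not settled at the AP foot "
            "(need >= %.1f ms)" % (settle + foot_lead)
        )
    if cfg.first_spike_latency_ms + geom["t_ret"] + 1.0 > cfg.step_duration_ms:
        raise ValueError("AP template does not fit within the current step")

    steps = np.asarray(cfg.current_steps_pA, dtype=float)
    V = np.empty((len(steps), n))
    spike_thr: Dict[int, List[float]] = {}
    spike_pk: Dict[int, List[float]] = {}

    for s, I in enumerate(steps):
        v = np.full(n, V0)
        in_step = (t >= t_on) & (t < t_off)
        post = t >= t_off
        if I < cfg.rheobase_pA:
            dV = I * R / 1000.0  # pA * MOhm -> mV
            v[in_step] = V0 + dV * (1.0 - np.exp(-(t[in_step] - t_on) / tau))
            if I < 0 and cfg.sag_mV:
                v[in_step] -= cfg.sag_mV * _alpha_bump(t[in_step] - t_on, cfg.sag_peak_ms)
            v_off = v[in_step][-1] if in_step.any() else V0
            v[post] = V0 + (v_off - V0) * np.exp(-(t[post] - t_off) / tau)
            if I < 0 and cfg.rebound_mV:
                v[post] += cfg.rebound_mV * _alpha_bump(t[post] - t_off, cfg.sag_peak_ms)
        else:
            v[in_step] = V0 + (plat - V0) * (1.0 - np.exp(-(t[in_step] - t_on) / tau_c))
            n_spikes = 1 + int((I - cfg.rheobase_pA) // cfg.extra_spike_per_pA)
            thr_times, pk_times = [], []
            for j in range(n_spikes):
                t_thr = t_on + cfg.first_spike_latency_ms + j * cfg.spike_interval_ms
                if t_thr + geom["t_ret"] + 1.0 > t_off:
                    break
                m = (t >= t_thr + geom["t_start"]) & (t <= min(t_thr + geom["t_end"], t_off))
                v[m] = tpl.evaluate(t[m] - t_thr)
                thr_times.append(t_thr)
                pk_times.append(t_thr + geom["t_pk"])
            spike_thr[s] = thr_times
            spike_pk[s] = pk_times
            v_off = v[in_step][-1] if in_step.any() else V0
            v[post] = V0 + (v_off - V0) * np.exp(-(t[post] - t_off) / tau)
        V[s] = v

    if cfg.noise_sd_mV > 0:
        V = V + rng.normal(0.0, cfg.noise_sd_mV, size=V.shape)

    sweeps = SweepSet(
        time_ms=t,
        voltage_mV=V,
        current_pA=steps,
        step_window_ms=(t_on, t_off),
        sampling_rate_hz=fs,
        meta={"seed": cfg.seed, "simulator": "v1phys.synthetic_data.ephys"},
    )

    spiking = sorted(spike_thr)
    first_ap = None
    if spiking:
        s0 = spiking[0]
        if spike_thr[s0]:
            first_ap = (s0, spike_thr[s0][0], spike_pk[s0][0])
    true_rheo = float(steps[steps >= cfg.rheobase_pA].min())
    feats = tpl.expected_features()
    truth = EphysGroundTruth(
        template_features=feats,
        membrane_R_MOhm=R,
        membrane_C_pF=cfg.membrane_C_pF,
        tau_ms=tau,
        rheobase_pA=true_rheo,
        spike_threshold_times_ms=spike_thr,
        spike_peak_times_ms=spike_pk,
        first_ap=first_ap,
        config=cfg,
    )
    return sweeps, truth
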