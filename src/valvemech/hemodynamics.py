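"""Transvalvular hemodynamic indices from pressure/flow waveforms.

Given one cardiac cycle of flow ``Q(t)`` (mL/s) and pressures (mmHg) with
the systolic/closure event times, the module computes:

* cycle volumes: forward volume ``V_F`` (systolic forward flow), regurgitant
  volume ``V_R`` (reverse flow during closing) and leakage volume ``V_L``
  (reverse flow after closure);
* regurgitant fraction ``RF = (V_R + V_L) / V_F * 100%``;
* mean systolic transvalvular pressure gradient
  ``TPG = mean(P_nlv - P_nao)`` over systole (mmHg);
* effective orifice area ``EOA = Q_rms / (51.6 sqrt(dP / rho))`` (cm^2) with
  ``Q_rms`` the systolic root-mean-square flow;
* left-ventricular energy loss
  ``E_L = 0.1333 * integral (P_ao - P_lv) Q dt`` over the cycle, reported as
  a magnitude in mJ (0.1333 converts mmHg*mL to mJ).

All integrals use trapezoidal quadrature with linear interpolation at the
event-window endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MMHG_ML_TO_MJ",
    "Events",
    "Waveform",
    "CycleVolumes",
    "cycle_volumes",
    "regurgitant_fraction",
    "mean_tpg",
    "q_rms",
    "eoa",
    "energy_loss",
    "detect_events",
    "all_indices",
]

#: mmHg*mL -> mJ (1 mmHg = 133.32 Pa, 1 mL = 1e-6 m^3), printed to 4 digits.
MMHG_ML_TO_MJ = 0.1333


@dataclass(frozen=True)
class Events:
    """Cycle event times (s): begin/end systole, full closure, cycle end."""

    t_bs: float
    t_es: float
    t_close: float
    t_cycle_end: float

    def __post_init__(self):
        if not (self.t_bs < self.t_es <= self.t_close < self.t_cycle_end):
            raise ValueError(
                "events must satisfy t_bs < t_es <= t_close < t_cycle_end"
            )


@dataclass(frozen=True)
class Waveform:
    """Sampled cycle: time (s), flow (mL/s), pressures (mmHg), events.

    ``P_nlv``/``P_nao`` are the near-valve pressures used for the gradient
    indices; when omitted they default to the inlet/outlet pressures
    ``P_lv``/``P_ao``.
    """

    t: np.ndarray
    Q: np.ndarray
    P_lv: Optional[np.ndarray] = None
    P_ao: Optional[np.ndarray] = None
    P_nlv: Optional[np.ndarray] = None
    P_nao: Optional[np.ndarray] = None
    events: Optional[Events] = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("t must be a 1-D array with at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        for name in ("Q", "P_lv", "P_ao", "P_nlv", "P_nao"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                if a.shape != t.shape:
                    raise ValueError(f"{name} must match t in shape")
                object.__setattr__(self, name, a)
        if self.events is not None:
            ev = self.events
            if ev.t_bs < t[0] - 1e-12 or ev.t_cycle_end > t[-1] + 1e-12:
                raise ValueError("event times must lie within the sampled window")

    @property
    def near_lv(self) -> np.ndarray:
        p = self.P_nlv if self.P_nlv is not None else self.P_lv
        if p is None:
            raise ValueError("waveform carries no LV-side pressure")
        return p

    @property
    def near_ao(self) -> np.ndarray:
        p = self.P_nao if self.P_nao is not None else self.P_ao
        if p is None:
            raise ValueError("waveform carries no aortic-side pressure")
        return p


@dataclass(frozen=True)
class CycleVolumes:
    """Forward, closing-regurgitant and leakage volumes (mL, magnitudes)."""

    V_F: float
    V_R: float
    V_L: float


def _window_integral(t: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of y over [a, b] with interpolated endpoints."""
    if b <= a:
        raise ValueError("integration window is empty")
    inside = (t > a) & (t < b)
    ts = np.concatenate([[a], t[inside], [b]])
    ys = np.concatenate([[np.interp(a, t, y)], y[inside], [np.interp(b, t, y)]])
    return float(np.trapezoid(ys, ts))


def cycle_volumes(w: Waveform) -> CycleVolumes:
    """Integrate forward flow over systole and reverse flow over the closing
    and leakage windows (trapezoidal)."""
    if w.events is None:
        raise ValueError("cycle volumes require event times")
    ev = w.events
    vf = _window_integral(w.t, np.maximum(w.Q, 0.0), ev.t_bs, ev.t_es)
    vr = 0.0
    if ev.t_close > ev.t_es:
        vr = _window_integral(w.t, np.maximum(-w.Q, 0.0), ev.t_es, ev.t_close)
    vl = _window_integral(w.t, np.maximum(-w.Q, 0.0), ev.t_close, ev.t_cycle_end)
    return CycleVolumes(V_F=vf, V_R=vr, V_L=vl)


def regurgitant_fraction(v: CycleVolumes) -> float:
    """RF = (V_R + V_L) / V_F * 100 (%)."""
    if v.V_F <= 0:
        raise ValueError("regurgitant fraction undefined for V_F <= 0")
    return (v.V_R + v.V_L) / v.V_F * 100.0


def mean_tpg(w: Waveform) -> float:
    """Systolic time-average of the near-valve gradient P_nlv - P_nao (mmHg)."""
    if w.events is None:
        raise ValueError("TPG requires event times")
    ev = w.events
    grad = w.near_lv - w.near_ao
    return _window_integral(w.t, grad, ev.t_bs, ev.t_es) / (ev.t_es - ev.t_bs)


def q_rms(w: Waveform) -> float:
    """Root-mean-square systolic flow rate (mL/s)."""
    if w.events is None:
        raise ValueError("Q_rms requires event times")
    ev = w.events
    msq = _window_integral(w.t, w.Q ** 2, ev.t_bs, ev.t_es) / (ev.t_es - ev.t_bs)
    return float(np.sqrt(msq))


def eoa(w: Waveform, delta_p: Optional[float] = None, rho: float = 1.0) -> float:
    """Effective orifice area Q_rms / (51.6 sqrt(dP/rho)) in cm^2.

    ``delta_p`` defaults to the mean systolic transvalvular gradient of the
    waveform; ``rho`` is the blood density in g/mL.
    """
    if delta_p is None:
        delta_p = mean_tpg(w)
    if delta_p <= 0:
        raise ValueError("EOA requires a positive mean pressure gradient")
    return q_rms(w) / (51.6 * np.sqrt(delta_p / rho))


def energy_loss(w: Waveform, signed: bool = False) -> float:
    """LV energy loss over the cycle (mJ).

    ``E_L = 0.1333 * integral (P_ao - P_lv) Q dt`` over [t_bs, t_cycle_end]
    when events are present, else the full sampled window.  The integral is
    negative for a valve doing net positive work on the blood; the magnitude
    is returned unless ``signed=True``.
    """
    if w.P_lv is None or w.P_ao is None:
        raise ValueError("energy loss requires P_lv and P_ao")
    a, b = (w.t[0], w.t[-1])
    if w.events is not None:
        a, b = w.events.t_bs, w.events.t_cycle_end
    integrand = (w.P_ao - w.P_lv) * w.Q
    el = MMHG_ML_TO_MJ * _window_integral(w.t, integrand, a, b)
    return el if signed else abs(el)


def detect_events(t, Q, zero_hold: float = 0.010, frac: float = 0.01) -> Events:
    """Heuristic event detection from the flow waveform alone.

    ``t_bs``/``t_es`` are the first/last crossings of Q through ``frac`` of
    its peak; ``t_close`` is the first time after ``t_es`` where ``|Q|``
    stays within ``frac`` of the peak for at least ``zero_hold`` seconds;
    the cycle ends at the final sample.
    """
    t = np.asarray(t, dtype=float)
    Q = np.asarray(Q, dtype=float)
    peak = float(Q.max())
    if peak <= 0:
        raise ValueError("no forward flow: cannot detect systole")
    thr = frac * peak
    above = np.nonzero(Q > thr)[0]
    t_bs = t[above[0]]
    t_es = t[above[-1]]
    # full closure: |Q| small for a sustained hold after end systole
    small = np.abs(Q) <= thr
    t_close = None
    idx = np.nonzero(t > t_es)[0]
    for i in idx:
        if small[i]:
            j = np.searchsorted(t, t[i] + zero_hold)
            if np.all(small[i:min(j + 1, len(t))]):
                t_close = t[i]
                break
    if t_close is None or t_close <= t_es:
        t_close = t_es + 1e-9 if t_es + 1e-9 < t[-1] else t_es
    return Events(t_bs=t_bs, t_es=t_es, t_close=t_close, t_cycle_end=t[-1])


def all_indices(w: Waveform, rho: float = 1.0) -> dict:
    """Convenience bundle: RF (%), TPG (mmHg), EOA (cm^2), E_L (mJ), volumes."""
    v = cycle_volumes(w)
    tpg = mean_tpg(w)
    return {
        "RF_percent": regurgitant_fraction(v),
        "TPG_mmHg": tpg,
        "EOA_cm2": eoa(w, delta_p=tpg, rho=rho),
        "EL_mJ": energy_loss(w),
        "V_F_mL": v.V_F,
        "V_R_mL": v.V_R,
        "V_L_mL": v.V_L,
    }
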