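"""Three-element Windkessel afterload model.

The stored pressure ``P_wk`` obeys ``C dP_wk/dt + P_wk / Rp = Q`` and the
outlet (aortic) pressure is ``P_ao = Q Rc + P_wk``, with ``Rc`` the
characteristic resistance (mmHg s/mL), ``Rp`` the peripheral resistance
(mmHg s/mL) and ``C`` the arterial compliance (mL/mmHg).  The flow ``Q`` is
positive out of the valve into the aorta; the distal reference pressure is
ground (zero).

Time stepping uses the exact exponential update for piecewise-constant flow,

    P_wk(t + dt) = Q Rp + (P_wk(t) - Q Rp) exp(-dt / (Rp C)),

which is unconditionally stable and free of integration error for sampled Q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["WindkesselParams", "step", "outlet_pressure", "simulate"]


@dataclass(frozen=True)
class WindkesselParams:
    """Afterload parameters; defaults are the human systemic values used for
    the aortic-valve model (time constant Rp*C = 1.3825 s)."""

    Rc: float = 0.033  # mmHg s / mL
    Rp: float = 0.79   # mmHg s / mL
    C: float = 1.75    # mL / mmHg
    Pwk0: float = 85.0  # mmHg, initial stored pressure

    def __post_init__(self):
        if self.Rc <= 0 or self.Rp <= 0 or self.C <= 0:
            raise ValueError("Rc, Rp and C must be positive")

    @property
    def tau(self) -> float:
        """Relaxation time constant Rp*C (s)."""
        return self.Rp * self.C


def step(params: WindkesselParams, Pwk: float, Q: float, dt: float) -> float:
    """Advance the stored pressure by dt (s) holding Q (mL/s) constant."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    qrp = Q * params.Rp
    return qrp + (Pwk - qrp) * np.exp(-dt / params.tau)


def outlet_pressure(params: WindkesselParams, Pwk, Q):
    """Aortic pressure P_ao = Q Rc + P_wk (mmHg); vectorized."""
    return np.asarray(Q) * params.Rc + np.asarray(Pwk)


def simulate(params: WindkesselParams, t, Q) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate over a sampled flow history.

    ``Q[k]`` is held constant on ``[t[k], t[k+1])`` (left-sampled,
    piecewise-constant).  Returns ``(Pwk, Pao)`` on the input grid, with
    ``Pwk[0] = params.Pwk0``.
    """
    t = np.asarray(t, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if t.shape != Q.shape:
        raise ValueError("t and Q must have the same shape")
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    n = t.size
    Pwk = np.empty(n)
    if n == 0:
        return Pwk, Pwk.copy()
    Pwk[0] = params.Pwk0
    if n > 1:
        dts = np.diff(t)
        decay = np.exp(-dts / params.tau)
        for k in range(n - 1):
            qrp = Q[k] * params.Rp
            Pwk[k + 1] = qrp + (Pwk[k] - qrp) * decay[k]
    Pao = outlet_pressure(params, Pwk, Q)
    return Pwk, np.asarray(Pao)
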