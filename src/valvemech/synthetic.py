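"""Synthetic inputs with the structure the analysis assumes.

Three generators cover the pipeline's inputs:

* **Biaxial datasets** emulating an equibiaxial (1:1) stress-controlled
  protocol: target Cauchy-stress levels rise linearly to a physiological
  peak set by Laplace's law for a thin spherical shell (valve radius of
  curvature 2 cm, transvalvular pressure 120 mmHg, leaflet thickness
  0.04 cm, ~400 kPa); the stretches realizing each stress level are found by
  2-D root finding on the planar-biaxial response, then multiplicative
  Gaussian noise is applied to the stresses.
* **Cycle waveforms** from a quasi-static lumped valve-afterload surrogate:
  a prescribed LV pressure pulse drives orifice flow
  ``Q = 51.6 * EOA_ref * A(t) * sign(dP) * sqrt(|dP|)`` through a
  time-varying opening fraction ``A(t)``, coupled to the three-element
  Windkessel afterload.  This deliberately simple phenomenological model
  stands in for full fluid-structure simulation output.
* **Leaflet meshes**: a semi-lunar cylindrical surface patch (tube radius
  1.3 cm) triangulated with labeled commissure corners, attachment halves
  and free edge.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root

from .biaxial import BiaxialDataset
from .constitutive import MaterialParams, planar_biaxial_stress
from .hemodynamics import Events, Waveform
from .meshes import LeafletMesh
from .windkessel import WindkesselParams, step as wk_step

__all__ = [
    "MMHG_TO_KPA",
    "BiaxialProtocol",
    "SurrogateCycleParams",
    "laplace_target_stress",
    "generate_biaxial",
    "add_noise",
    "generate_waveforms",
    "generate_leaflet_mesh",
]

#: mmHg -> kPa (1 mmHg = 0.13332 kPa).
MMHG_TO_KPA = 0.13332


def laplace_target_stress(
    radius_cm: float = 2.0, pressure_mmhg: float = 120.0, thickness_cm: float = 0.04
) -> float:
    """Thin-spherical-shell wall stress sigma = P r / (2 h) in kPa.

    Defaults give the physiological peak used by the stress-controlled
    biaxial protocol: 0.13332 * 120 * 2 / 0.08 = 399.96 kPa.
    """
    if radius_cm <= 0 or pressure_mmhg <= 0 or thickness_cm <= 0:
        raise ValueError("radius, pressure and thickness must be positive")
    return MMHG_TO_KPA * pressure_mmhg * radius_cm / (2.0 * thickness_cm)


@dataclass(frozen=True)
class BiaxialProtocol:
    """Loading protocol for synthetic biaxial tests."""

    mode: str = "equibiaxial-stress"  # or "equibiaxial-stretch"
    peak_stress: float = field(default_factory=laplace_target_stress)  # kPa
    n_points: int = 25
    noise_cv: float = 0.0  # multiplicative Gaussian coefficient of variation
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("equibiaxial-stress", "equibiaxial-stretch"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.peak_stress <= 0:
            raise ValueError("peak_stress must be positive")
        if self.n_points < 10:
            raise ValueError("n_points must be at least 10")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def _solve_equibiaxial_stress(params: MaterialParams, levels: np.ndarray):
    """Stretches (lambda1, lambda2) realizing sigma11 = sigma22 = s for each
    target level, by continuation from the reference state."""
    y = np.array([0.01, 0.01])  # log-stretches: positivity by construction
    out = np.empty((len(levels), 2))
    for i, s in enumerate(levels):
        def resid(yy):
            s11, s22 = planar_biaxial_stress(params, np.exp(yy[0]), np.exp(yy[1]))
            return [s11 - s, s22 - s]

        sol = root(resid, y, method="hybr", tol=1e-12)
        if not sol.success or np.abs(resid(sol.x)).max() > 1e-6 * max(1.0, s):
            sol = root(resid, y, method="lm")  # stiff-exponential fallback
        if np.abs(resid(sol.x)).max() > 1e-6 * max(1.0, s):
            raise RuntimeError(
                f"equibiaxial stress solve failed at level {s:.3g} kPa"
            )
        y = sol.x
        out[i] = np.exp(y)
    return out[:, 0], out[:, 1]


def generate_biaxial(
    params: MaterialParams, proto: BiaxialProtocol = BiaxialProtocol(),
    sample_id: str = "synthetic",
) -> BiaxialDataset:
    """Synthesize one biaxial sample from a constitutive law and protocol.

    Stress-controlled mode solves for the stretch path that keeps the two
    in-plane stresses equal at each level in ``linspace(0, peak]``; the
    noiseless output therefore reproduces the generating law exactly.
    """
    if proto.mode == "equibiaxial-stress":
        levels = proto.peak_stress * np.arange(1, proto.n_points + 1) / proto.n_points
        l1, l2 = _solve_equibiaxial_stress(params, levels)
    else:
        # equal-stretch path sized so the fiber stress reaches ~peak_stress
        lam_max = _stretch_for_peak(params, proto.peak_stress)
        lam = np.linspace(1.0, lam_max, proto.n_points + 1)[1:]
        l1 = l2 = lam
    s11, s22 = planar_biaxial_stress(params, l1, l2)
    data = BiaxialDataset(sample_id, l1, l2, s11, s22)
    if proto.noise_cv > 0:
        data = add_noise(data, proto.noise_cv, np.random.default_rng(proto.seed))
    return data


def _stretch_for_peak(params: MaterialParams, peak: float) -> float:
    from scipy.optimize import brentq

    def f(lam):
        s11, _ = planar_biaxial_stress(params, lam, lam)
        return s11 - peak

    hi = 1.05
    while f(hi) < 0 and hi < 4.0:
        hi *= 1.05
    return brentq(f, 1.0 + 1e-9, hi)


def add_noise(data: BiaxialDataset, cv: float, rng: np.random.Generator) -> BiaxialDataset:
    """Multiplicative Gaussian measurement noise on both stress channels."""
    f11 = 1.0 + cv * rng.standard_normal(data.n)
    f22 = 1.0 + cv * rng.standard_normal(data.n)
    return BiaxialDataset(
        data.sample_id, data.lambda1, data.lambda2,
        data.sigma11 * f11, data.sigma22 * f22,
    )


# ---------------------------------------------------------------------------
# cycle waveform surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateCycleParams:
    """Quasi-static valve-afterload surrogate parameters.

    The LV pressure is a smooth systolic pulse on a diastolic baseline; the
    opening fraction ramps open over ``t_opening`` s, stays fully open, then
    ramps down to a small leak fraction over ``t_closing`` s.  ``eoa_ref`` is
    the fully-open reference orifice area (cm^2) entering the orifice
    equation ``Q = 51.6 * eoa_ref * A * sqrt(|dP|)``.
    """

    period: float = 0.8          # s, one cardiac cycle
    dt: float = 2e-4             # s, integration step
    p_diastolic: float = 12.0    # mmHg, LV baseline
    p_peak: float = 110.0        # mmHg, LV systolic peak
    t_sys_start: float = 0.05    # s, LV pulse onset
    t_sys: float = 0.42          # s, LV pulse duration
    t_opening: float = 0.09      # s, valve opening ramp
    t_preclose: float = 0.22     # s, start of the closing ramp
    t_closing: float = 0.16      # s, valve closing ramp
    eoa_ref: float = 4.0         # cm^2, fully-open reference orifice area
    leak_fraction: float = 0.004  # residual opening after closure
    noise_cv: float = 0.0        # optional multiplicative flow noise
    wk: WindkesselParams = field(default_factory=WindkesselParams)

    def __post_init__(self):
        if self.period <= 0 or self.dt <= 0:
            raise ValueError("period and dt must be positive")
        if self.p_peak <= self.p_diastolic or self.p_diastolic <= 0:
            raise ValueError("require 0 < p_diastolic < p_peak")


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _lv_pressure(p: SurrogateCycleParams, t: np.ndarray) -> np.ndarray:
    phase = (t - p.t_sys_start) / p.t_sys
    pulse = np.where(
        (phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)) ** 2, 0.0
    )
    return p.p_diastolic + (p.p_peak - p.p_diastolic) * pulse


def _opening_fraction(p: SurrogateCycleParams, t: np.ndarray) -> np.ndarray:
    t_open = p.t_sys_start + 0.01
    up = _smoothstep((t - t_open) / p.t_opening)
    down = _smoothstep((t - p.t_preclose) / p.t_closing)
    A = up * (1.0 - down)
    return p.leak_fraction + (1.0 - p.leak_fraction) * A


def _orifice_flow(dp: float, k: float, Rc: float) -> float:
    """Solve Q = k * sign(d) * sqrt(|d - Rc Q|) for the self-consistent flow
    through the orifice in series with the characteristic resistance."""
    if k <= 0 or dp == 0:
        return 0.0
    sgn = 1.0 if dp > 0 else -1.0
    d = abs(dp)
    c = k * k * Rc
    q = 0.5 * (-c + np.sqrt(c * c + 4.0 * k * k * d))
    return sgn * q


def generate_waveforms(
    params: SurrogateCycleParams = SurrogateCycleParams(), seed: int = 0
) -> Waveform:
    """One cardiac cycle of (Q, P_lv, P_ao) from the lumped surrogate.

    The waveform carries detected event times; with default parameters the
    forward volume lands in the physiological 60-100 mL design band and the
    indices are finite and plausible.  Deterministic given ``seed``.
    """
    n = int(round(params.period / params.dt)) + 1
    t = np.linspace(0.0, params.period, n)
    plv = _lv_pressure(params, t)
    A = _opening_fraction(params, t)
    rng = np.random.default_rng(seed)

    Q = np.zeros(n)
    pwk = np.zeros(n)
    pao = np.zeros(n)
    pwk[0] = params.wk.Pwk0
    for i in range(n):
        k = 51.6 * params.eoa_ref * A[i]
        q = _orifice_flow(plv[i] - pwk[i], k, params.wk.Rc)
        if params.noise_cv > 0:
            q *= 1.0 + params.noise_cv * rng.standard_normal()
        Q[i] = q
        pao[i] = q * params.wk.Rc + pwk[i]
        if i + 1 < n:
            pwk[i + 1] = wk_step(params.wk, pwk[i], q, t[i + 1] - t[i])

    from .hemodynamics import detect_events

    if np.max(Q) > 0:
        events = detect_events(t, Q)
    else:
        events = None
    return Waveform(t=t, Q=Q, P_lv=plv, P_ao=pao, events=events)


# ---------------------------------------------------------------------------
# leaflet surface mesh
# ---------------------------------------------------------------------------

def generate_leaflet_mesh(
    resolution: int = 16,
    radius: float = 1.3,
    depth: float = 1.2,
    sector: float = 2.0 * np.pi / 3.0,
) -> LeafletMesh:
    """Semi-lunar leaflet patch on a cylinder of the aortic-tube radius (cm).

    The attachment edge dips to ``depth`` below the commissures at the belly
    center; the free edge is the horizontal arc joining the two commissures.
    Returned with labels: commissure corners ``n1``/``n2``, attachment
    halves ``tau1`` (toward n1) / ``tau2`` (toward n2), and the free edge.
    """
    if resolution < 4:
        raise ValueError("resolution must be at least 4")
    m = 2 * resolution + 1  # odd circumferential count: symmetric halves
    nv = resolution + 1
    half = sector / 2.0
    theta = np.linspace(-half, half, m)
    z_att = -depth * np.cos(np.pi * theta / sector) ** 1.0  # 0 at commissures

    # structured grid, columns collapse at the commissures; weld duplicates
    verts = []
    vid = {}
    grid = np.empty((m, nv), dtype=int)
    for i in range(m):
        for j in range(nv):
            z = z_att[i] * (1.0 - j / resolution)
            key = (round(theta[i], 12), round(z, 12))
            if key not in vid:
                vid[key] = len(verts)
                verts.append(
                    (radius * np.sin(theta[i]), radius * np.cos(theta[i]), z)
                )
            grid[i, j] = vid[key]
    verts = np.array(verts)

    tris = []
    for i in range(m - 1):
        for j in range(nv - 1):
            a, b = grid[i, j], grid[i + 1, j]
            c, d = grid[i + 1, j + 1], grid[i, j + 1]
            for tri in ((a, b, c), (a, c, d)):
                if len(set(tri)) == 3:
                    tris.append(tri)
    tris = np.array(tris, dtype=int)

    n1 = grid[0, nv - 1]
    n2 = grid[m - 1, nv - 1]
    att = [grid[i, 0] for i in range(m)]
    tau1 = np.array([v for i, v in enumerate(att) if theta[i] < 0 and v not in (n1, n2)])
    tau2 = np.array([v for i, v in enumerate(att) if theta[i] > 0 and v not in (n1, n2)])
    free = np.array(
        sorted({grid[i, nv - 1] for i in range(m)} - {n1, n2}), dtype=int
    )
    return LeafletMesh(
        vertices=verts, triangles=tris, n1=int(n1), n2=int(n2),
        tau1=tau1, tau2=tau2, free_edge=free,
    )
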