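"""Anisotropic hyperelastic constitutive laws for aortic-valve leaflet tissue.

Three incompressible, fiber-reinforced strain-energy functions are provided,
denoted W1, W2 and W3.  Each is a function of the first invariant
``I1 = tr(C)`` of the right Cauchy-Green tensor ``C = F^T F`` and of the
squared fiber stretch ``I4 = f0 . (C f0)``:

* ``W1 = C10 (exp(C01 (I1-3)) - 1) + k1/(2 k2) [exp(k2 (I4-1)^2) - 1]``
  -- exponential response in both the fiber and cross-fiber directions;
* ``W2 = mu (I1-3) + c0 [exp(c1 (I1-3)^2 + c2 (I4-1)^4) - 1]``
  -- neo-Hookean ground matrix plus a coupled exponential term;
* ``W3 = C1 (I1-3) + a/(2 b) [exp(b (I4-1)^2) - 1]``
  -- linear cross-fiber response, exponential fiber response.

The Cauchy stress of each law has the common structure

    sigma = -p I + alpha(I1, I4) B + beta(I1, I4) f (x) f,

with ``B = F F^T`` the left Cauchy-Green tensor, ``f = F f0`` the deformed
fiber direction and ``p`` the Lagrange-multiplier pressure enforcing
incompressibility.  All stresses and stress-like parameters are in kPa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "LAWS",
    "PARAM_NAMES",
    "MaterialParams",
    "DeformationState",
    "StressState",
    "deformation_from_stretches",
    "strain_energy",
    "stress_coefficients",
    "cauchy_stress",
    "piola_from_cauchy",
    "cauchy_from_piola",
    "planar_biaxial_stress",
    "fiber_strain",
    "fiber_stress",
    "curve_to_csv",
]

LAWS = ("W1", "W2", "W3")

#: Named parameters of each law, in the order used for fitting vectors.
PARAM_NAMES = {
    "W1": ("C10", "C01", "k1", "k2"),
    "W2": ("mu", "c0", "c1", "c2"),
    "W3": ("C1", "a", "b"),
}

# maximum argument passed to np.exp inside residual evaluations; physical
# parameter ranges stay far below this, it only guards multi-start initials
_EXP_CAP = 60.0


@dataclass(frozen=True)
class MaterialParams:
    """Non-negative parameter set of one constitutive law.

    ``values`` maps the law's parameter names (see :data:`PARAM_NAMES`) to
    their values; stress-like parameters are in kPa, exponents dimensionless.
    """

    law: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.law not in LAWS:
            raise ValueError(f"unknown law {self.law!r}; expected one of {LAWS}")
        names = PARAM_NAMES[self.law]
        if set(self.values) != set(names):
            raise ValueError(
                f"law {self.law} requires parameters {names}, got {tuple(self.values)}"
            )
        for k, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {k}={v} must be finite and >= 0")

    # -- constructors -------------------------------------------------
    @classmethod
    def w1(cls, C10: float, C01: float, k1: float, k2: float) -> "MaterialParams":
        return cls("W1", {"C10": C10, "C01": C01, "k1": k1, "k2": k2})

    @classmethod
    def w2(cls, mu: float, c0: float, c1: float, c2: float) -> "MaterialParams":
        # 'mu' is the ground-matrix shear modulus of law W2 (kPa), not a
        # fluid viscosity; exposed as mu_w2 in vector form for clarity
        return cls("W2", {"mu": mu, "c0": c0, "c1": c1, "c2": c2})

    @classmethod
    def w3(cls, C1: float, a: float, b: float) -> "MaterialParams":
        return cls("W3", {"C1": C1, "a": a, "b": b})

    @classmethod
    def from_vector(cls, law: str, x) -> "MaterialParams":
        names = PARAM_NAMES[law]
        x = np.asarray(x, dtype=float)
        if x.shape != (len(names),):
            raise ValueError(f"law {law} expects {len(names)} parameters")
        return cls(law, dict(zip(names, x)))

    # -- views ---------------------------------------------------------
    def as_vector(self) -> np.ndarray:
        return np.array([self.values[k] for k in PARAM_NAMES[self.law]], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_json(self) -> str:
        return json.dumps({"law": self.law, "params": self.values, "units": "kPa"})

    @classmethod
    def from_json(cls, text: str) -> "MaterialParams":
        d = json.loads(text)
        return cls(d["law"], dict(d["params"]))


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient plus reference fiber direction, with derived
    kinematic quantities (J, C, B, I1, I4, Green strain E, deformed fiber f)."""

    F: np.ndarray
    f0: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        f0 = np.asarray(self.f0, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        n = np.linalg.norm(f0)
        if abs(n - 1.0) > 1e-8:
            raise ValueError("f0 must be a unit vector")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "f0", f0)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def B(self) -> np.ndarray:
        return self.F @ self.F.T

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I4(self) -> float:
        return float(self.f0 @ self.C @ self.f0)

    @property
    def E(self) -> np.ndarray:
        """Green-Lagrange strain (C - I)/2."""
        return 0.5 * (self.C - np.eye(3))

    @property
    def f(self) -> np.ndarray:
        """Deformed (push-forward) fiber direction F f0, magnitude sqrt(I4)."""
        return self.F @ self.f0


@dataclass(frozen=True)
class StressState:
    """Symmetric Cauchy stress (kPa) together with the pressure p used."""

    sigma: np.ndarray
    p: float

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (3, 3):
            raise ValueError("sigma must be 3x3")
        if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
            raise ValueError("sigma must be symmetric")
        object.__setattr__(self, "sigma", 0.5 * (s + s.T))


def deformation_from_stretches(lambda1: float, lambda2: float) -> DeformationState:
    """Incompressible shear-free biaxial kinematics.

    F = diag(lambda1, lambda2, 1/(lambda1*lambda2)) with the fiber along the
    first (circumferential) axis, so J = 1 exactly and I4 = lambda1**2.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("stretches must be positive")
    F = np.diag([lambda1, lambda2, 1.0 / (lambda1 * lambda2)])
    return DeformationState(F=F, f0=np.array([1.0, 0.0, 0.0]))


def _exp(x):
    return np.exp(np.minimum(x, _EXP_CAP))


def strain_energy(params: MaterialParams, state: DeformationState) -> float:
    """Strain-energy density W(I1, I4) in kPa; zero at the reference state."""
    I1, I4 = state.I1, state.I4
    q1 = I1 - 3.0
    q4 = I4 - 1.0
    v = params.values
    if params.law == "W1":
        W = v["C10"] * (_exp(v["C01"] * q1) - 1.0)
        if v["k2"] > 0:
            W += v["k1"] / (2.0 * v["k2"]) * (_exp(v["k2"] * q4 ** 2) - 1.0)
        else:  # limit k2 -> 0: k1/2 * (I4-1)^2
            W += 0.5 * v["k1"] * q4 ** 2
        return float(W)
    if params.law == "W2":
        return float(
            v["mu"] * q1 + v["c0"] * (_exp(v["c1"] * q1 ** 2 + v["c2"] * q4 ** 4) - 1.0)
        )
    # W3
    W = v["C1"] * q1
    if v["b"] > 0:
        W += v["a"] / (2.0 * v["b"]) * (_exp(v["b"] * q4 ** 2) - 1.0)
    else:
        W += 0.5 * v["a"] * q4 ** 2
    return float(W)


def stress_coefficients(params: MaterialParams, I1, I4) -> Tuple[np.ndarray, np.ndarray]:
    """Coefficients (alpha, beta) of sigma = -p I + alpha B + beta f(x)f.

    alpha = 2 dW/dI1 and beta = 2 dW/dI4; vectorized over I1, I4.
    """
    I1 = np.asarray(I1, dtype=float)
    I4 = np.asarray(I4, dtype=float)
    q1 = I1 - 3.0
    q4 = I4 - 1.0
    v = params.values
    if params.law == "W1":
        alpha = 2.0 * v["C10"] * v["C01"] * _exp(v["C01"] * q1)
        beta = 2.0 * v["k1"] * q4 * _exp(v["k2"] * q4 ** 2)
    elif params.law == "W2":
        e = _exp(v["c1"] * q1 ** 2 + v["c2"] * q4 ** 4)
        alpha = 2.0 * v["mu"] + 4.0 * v["c0"] * v["c1"] * q1 * e
        beta = 8.0 * v["c0"] * v["c2"] * q4 ** 3 * e
    else:  # W3
        alpha = 2.0 * v["C1"] * np.ones_like(q1)
        beta = 2.0 * v["a"] * q4 * _exp(v["b"] * q4 ** 2)
    return alpha, beta


def cauchy_stress(params: MaterialParams, state: DeformationState, p: float) -> StressState:
    """Cauchy stress sigma = -p I + alpha B + beta f(x)f (kPa)."""
    if not np.isfinite(p):
        raise ValueError("pressure p must be finite")
    alpha, beta = stress_coefficients(params, state.I1, state.I4)
    f = state.f
    sigma = -p * np.eye(3) + float(alpha) * state.B + float(beta) * np.outer(f, f)
    return StressState(sigma=sigma, p=float(p))


def piola_from_cauchy(state: DeformationState, sigma: np.ndarray) -> np.ndarray:
    """First Piola-Kirchhoff stress P = J sigma F^{-T}."""
    J = state.J
    if J <= 0 or not np.isfinite(J):
        raise ValueError("deformation gradient must have positive determinant")
    return J * np.asarray(sigma, dtype=float) @ np.linalg.inv(state.F).T


def cauchy_from_piola(state: DeformationState, P: np.ndarray) -> np.ndarray:
    """Inverse map sigma = J^{-1} P F^T."""
    J = state.J
    if J <= 0 or not np.isfinite(J):
        raise ValueError("deformation gradient must have positive determinant")
    return np.asarray(P, dtype=float) @ state.F.T / J


def planar_biaxial_stress(params: MaterialParams, lambda1, lambda2):
    """In-plane Cauchy stresses of an incompressible planar-biaxial state.

    With lambda3 = 1/(lambda1*lambda2) and the plane-stress condition
    sigma33 = 0, the pressure is eliminated analytically, p = alpha*lambda3^2,
    leaving

        sigma11 = alpha (lambda1^2 - lambda3^2) + beta lambda1^2,
        sigma22 = alpha (lambda2^2 - lambda3^2).

    Vectorized over stretch arrays; returns ``(sigma11, sigma22)`` in kPa.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    l3 = 1.0 / (l1 * l2)
    I1 = l1 ** 2 + l2 ** 2 + l3 ** 2
    I4 = l1 ** 2
    alpha, beta = stress_coefficients(params, I1, I4)
    s11 = alpha * (l1 ** 2 - l3 ** 2) + beta * l1 ** 2
    s22 = alpha * (l2 ** 2 - l3 ** 2)
    if s11.ndim == 0:
        return float(s11), float(s22)
    return s11, s22


def fiber_strain(state: DeformationState) -> float:
    """Fiber strain f0 . (E f0) = (I4 - 1)/2."""
    return float(state.f0 @ state.E @ state.f0)


def fiber_stress(state: DeformationState, sigma: np.ndarray) -> float:
    """Normal Cauchy stress along the deformed fiber, fhat . (sigma fhat).

    The deformed direction F f0 is normalized before the quadratic form so
    the result is a true normal stress (traction component), independent of
    the fiber stretch magnitude.
    """
    f = state.f
    n = np.linalg.norm(f)
    if n < 1e-14:
        raise ValueError("deformed fiber direction has zero length")
    fhat = f / n
    return float(fhat @ np.asarray(sigma, dtype=float) @ fhat)


def curve_to_csv(path, lambda1, lambda2, sigma11, sigma22) -> None:
    """Write a stretch-stress curve as CSV with the standard header."""
    arr = np.column_stack([lambda1, lambda2, sigma11, sigma22])
    np.savetxt(
        path, arr, delimiter=",", comments="",
        header="lambda1,lambda2,sigma11_kPa,sigma22_kPa", fmt="%.10g",
    )
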