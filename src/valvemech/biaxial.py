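"""Calibration of leaflet constitutive parameters to planar biaxial data.

The loss is the unweighted sum of squared Cauchy-stress residuals in both
in-plane directions,

    f(theta) = sum_i [ (sigma11_model - sigma11_exp)^2
                     + (sigma22_model - sigma22_exp)^2 ],

minimized subject to theta >= 0 (all material parameters non-negative) by a
bound-constrained trust-region least-squares solver with seeded multi-start
(exponential laws have local minima).  Goodness of fit is reported as
R^2 = 1 - SSE/SST with SST pooled over both stress components, plus a
per-sample RMSE "average error" sqrt(SSE / 2n) in kPa.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constitutive import LAWS, PARAM_NAMES, MaterialParams, planar_biaxial_stress

__all__ = [
    "BiaxialDataset",
    "FitResult",
    "Goodness",
    "loss",
    "fit_parameters",
    "goodness",
    "aggregate_samples",
]

# multi-start initials: each parameter log-uniform in [1e-2, 1e3]
_INIT_LO, _INIT_HI = 1e-2, 1e3


@dataclass(frozen=True)
class BiaxialDataset:
    """One biaxial test sample: stretches and measured Cauchy stresses (kPa)."""

    sample_id: str
    lambda1: np.ndarray
    lambda2: np.ndarray
    sigma11: np.ndarray
    sigma22: np.ndarray

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "sigma11", "sigma22"):
            a = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, a)
        n = len(self.lambda1)
        if not all(len(getattr(self, k)) == n for k in ("lambda2", "sigma11", "sigma22")):
            raise ValueError("all data columns must have equal length")
        if np.any(self.lambda1 <= 0) or np.any(self.lambda2 <= 0):
            raise ValueError("stretches must be positive")
        if not (np.all(np.isfinite(self.sigma11)) and np.all(np.isfinite(self.sigma22))):
            raise ValueError("stresses must be finite")

    @property
    def n(self) -> int:
        return len(self.lambda1)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.lambda1, self.lambda2, self.sigma11, self.sigma22])
        np.savetxt(
            path, arr, delimiter=",", comments="",
            header=f"# sample_id: {self.sample_id}\nlambda1,lambda2,sigma11_kPa,sigma22_kPa",
            fmt="%.10g",
        )

    @classmethod
    def from_csv(cls, path, sample_id: Optional[str] = None) -> "BiaxialDataset":
        sid = sample_id
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            s = ln.strip()
            if s.startswith("#"):
                if "sample_id:" in s and sid is None:
                    sid = s.split("sample_id:")[1].strip()
                continue
            if s and not s[0].isalpha():
                body.append(s)
        arr = np.array([[float(x) for x in ln.split(",")] for ln in body])
        return cls(sid or str(path), arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


@dataclass
class Goodness:
    sse: float
    sst: float
    r_squared: float  # NaN when SST == 0 (degenerate data)
    avg_error: float  # RMSE sqrt(SSE / 2n), kPa

    @property
    def r_squared_defined(self) -> bool:
        return not math.isnan(self.r_squared)


@dataclass
class FitResult:
    params: MaterialParams
    sse: float
    r_squared: float
    avg_error: float
    converged: bool
    n_iter: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = {"law": self.params.law, "values": dict(self.params.values)}
        return d


def _residuals(x: np.ndarray, law: str, data: BiaxialDataset) -> np.ndarray:
    p = MaterialParams.from_vector(law, np.maximum(x, 0.0))
    s11, s22 = planar_biaxial_stress(p, data.lambda1, data.lambda2)
    r = np.concatenate([s11 - data.sigma11, s22 - data.sigma22])
    return np.nan_to_num(r, nan=1e12, posinf=1e12, neginf=-1e12)


def loss(params: MaterialParams, data: BiaxialDataset) -> float:
    """Sum of squared stress residuals over both directions (kPa^2)."""
    r = _residuals(params.as_vector(), params.law, data)
    return float(r @ r)


def goodness(params: MaterialParams, data: BiaxialDataset) -> Goodness:
    """SSE, pooled SST, R^2 and RMSE of a parameter set on one sample."""
    sse = loss(params, data)
    pooled = np.concatenate([data.sigma11, data.sigma22])
    sst = float(np.sum((pooled - pooled.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    return Goodness(sse=sse, sst=sst, r_squared=r2,
                    avg_error=math.sqrt(sse / (2 * data.n)))


def fit_parameters(
    law: str,
    data: BiaxialDataset,
    init: Optional[MaterialParams] = None,
    n_restarts: int = 20,
    seed: Optional[int] = 0,
    ftol: float = 1e-10,
    max_nfev: int = 5000,
) -> FitResult:
    """Bound-constrained least-squares calibration with seeded multi-start.

    Starts from ``init`` (when given) plus ``n_restarts`` random initials with
    each parameter log-uniform in [1e-2, 1e3]; the best converged local
    solution is returned.  If no start converges the best-so-far solution is
    returned with ``converged=False``.
    """
    if law not in LAWS:
        raise ValueError(f"unknown law {law!r}")
    k = len(PARAM_NAMES[law])
    if data.n < k:
        raise ValueError(f"need at least {k} points to fit law {law}")
    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        if init.law != law:
            raise ValueError("init parameters are for a different law")
        starts.append(init.as_vector())
    starts.extend(
        np.exp(rng.uniform(np.log(_INIT_LO), np.log(_INIT_HI), size=k))
        for _ in range(n_restarts)
    )

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals, x0, args=(law, data), bounds=(0.0, np.inf),
                method="trf", ftol=ftol, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception:
            continue
        cand = (float(sol.cost) * 2.0, sol)  # least_squares cost = SSE/2
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    sse, sol = best
    params = MaterialParams.from_vector(law, np.maximum(sol.x, 0.0))
    g = goodness(params, data)
    return FitResult(
        params=params, sse=g.sse, r_squared=g.r_squared, avg_error=g.avg_error,
        converged=bool(sol.success), n_iter=int(sol.nfev),
    )


def aggregate_samples(fits: Sequence[FitResult]) -> dict:
    """Across-sample summary: mean +- SD of the RMSE, mean R^2, mean params.

    Mirrors reporting fitted parameters per sample and then averaging over
    samples; SD is the sample standard deviation (ddof=1), zero for a single
    fit by convention.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit to aggregate")
    law = fits[0].params.law
    if any(f.params.law != law for f in fits):
        raise ValueError("all fits must use the same law")
    errs = np.array([f.avg_error for f in fits])
    r2s = np.array([f.r_squared for f in fits])
    mat = np.vstack([f.params.as_vector() for f in fits])
    return {
        "law": law,
        "n_samples": len(fits),
        "avg_error_mean": float(errs.mean()),
        "avg_error_sd": float(errs.std(ddof=1)) if len(fits) > 1 else 0.0,
        "r_squared_mean": float(np.nanmean(r2s)),
        "params_mean": dict(zip(PARAM_NAMES[law], mat.mean(axis=0))),
    }


def fits_to_json(fits: Iterable[FitResult], path=None) -> str:
    """Serialize fits plus the aggregate block as JSON."""
    fits = list(fits)
    out = {"fits": [f.to_dict() for f in fits], "aggregate": aggregate_samples(fits)}
    text = json.dumps(out, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
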