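"""Classical ACVF-based Hurst estimators: lag-1 inversion (M1) and least squares (M2).

M1 inverts the lag-1 fGn autocovariance γ(1) = (D/2)(2^{2H} − 2) in closed
form:

    Ĥ = (1/2) log₂(2 γ̂(1)/D + 2).

When D is unknown it is replaced by the sample variance of the increments,
taken as γ̂(0) (the biased mean-of-squares, consistent with the divisor-n
ACVF convention). The logarithm's argument must be positive; strongly
negative γ̂(1) (possible by sampling noise for small H) makes the estimate
undefined, reported as ``valid=False`` rather than raised.

M2 fits the model curve τ ↦ (D/2)(|τ+1|^{2H} + |τ−1|^{2H} − 2|τ|^{2H}) to the
sample ACVF over lags 1..τmax by nonlinear least squares in H, with D either
known or profiled out in closed form (the model is linear in D, so for each
candidate H the optimal D̂(H) = Σγ̂g / Σg² with g the unit-D curve). With D
estimated, lag 0 joins the objective — it then carries scale information.
The 1-D objective can be multi-modal for noisy ACVFs, so the search runs
bounded derivative-free (Brent) refinements on a partition of (0, 1) and
keeps the global best, breaking ties toward the smaller Ĥ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .acvf import ACVFVector

__all__ = ["EPS_H", "HurstEstimate", "M2Config", "estimate_m1", "estimate_m2"]

EPS_H = 1e-6  # clipping margin keeping estimates strictly inside (0, 1)


@dataclass(frozen=True)
class HurstEstimate:
    """A Hurst exponent estimate with method tag and validity bookkeeping.

    ``valid`` is False only when the method's domain precondition failed
    (M1's log argument ≤ 0, or M2's jointly estimated D collapsing to the
    zero boundary); ``clipped`` marks estimates pulled back to
    [EPS_H, 1 − EPS_H], with the raw value retained in ``raw_hurst``.
    """

    hurst_hat: float
    method: str
    valid: bool = True
    diffusion_hat: float | None = None
    objective: float | None = None
    clipped: bool = False
    raw_hurst: float | None = None

    def to_dict(self) -> dict:
        return {
            "hurst_hat": self.hurst_hat,
            "method": self.method,
            "valid": self.valid,
            "diffusion_hat": self.diffusion_hat,
            "objective": self.objective,
            "clipped": self.clipped,
            "raw_hurst": self.raw_hurst,
        }


@dataclass(frozen=True)
class M2Config:
    """Settings for the least-squares fit.

    tau_max : highest lag entering the objective (≥ 1; ≥ 2 recommended —
        at τmax = 1 the fit degenerates to M1's single equation).
    estimate_diffusion : jointly estimate D (profiled in closed form).
    include_lag0 : force lag 0 into the objective; default (None) follows
        the convention "lag 0 iff D is estimated".
    tol : absolute tolerance on Ĥ for the bounded scalar refinements.
    n_grid_starts : number of equal subintervals of (0, 1), each refined.
    """

    tau_max: int = 31
    estimate_diffusion: bool = False
    include_lag0: bool | None = None
    tol: float = 1e-6
    n_grid_starts: int = 21

    def __post_init__(self) -> None:
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if not 0.0 < self.tol <= 1e-2:
            raise ValueError("tol must lie in (0, 1e-2]")
        if self.n_grid_starts < 1:
            raise ValueError("n_grid_starts must be >= 1")


def _clip_h(h: float) -> tuple[float, bool]:
    if h < EPS_H:
        return EPS_H, True
    if h > 1.0 - EPS_H:
        return 1.0 - EPS_H, True
    return h, False


def estimate_m1(
    acvf: ACVFVector, diffusion: float | None = None, clip: bool = True
) -> HurstEstimate:
    """Closed-form lag-1 estimator Ĥ = (1/2) log₂(2 γ̂(1)/D + 2).

    If ``diffusion`` is None it is estimated as the sample variance of the
    increments, γ̂(0). A nonpositive log argument yields ``valid=False``
    with ``hurst_hat`` NaN instead of an exception.
    """
    if len(acvf) < 2:
        raise ValueError("M1 requires the ACVF at lag 1")
    gamma1 = float(acvf.values[1])
    d_hat = None
    if diffusion is None:
        d_hat = float(acvf.values[0])
        diffusion = d_hat
    if diffusion <= 0:
        return HurstEstimate(hurst_hat=np.nan, method="M1", valid=False,
                             diffusion_hat=d_hat)
    arg = 2.0 * gamma1 / diffusion + 2.0
    if arg <= 0.0:
        return HurstEstimate(hurst_hat=np.nan, method="M1", valid=False,
                             diffusion_hat=d_hat)
    raw = 0.5 * np.log2(arg)
    if clip:
        h, clipped = _clip_h(raw)
    else:
        h, clipped = raw, False
    return HurstEstimate(hurst_hat=h, method="M1", valid=True,
                         diffusion_hat=d_hat, clipped=clipped,
                         raw_hurst=raw if clipped else None)


def _unit_curve(taus: np.ndarray, h: float) -> np.ndarray:
    """Model ACVF at D = 1: (1/2)(|τ+1|^{2H} + |τ−1|^{2H} − 2|τ|^{2H})."""
    two_h = 2.0 * h
    return 0.5 * (
        np.abs(taus + 1.0) ** two_h
        + np.abs(taus - 1.0) ** two_h
        - 2.0 * np.abs(taus) ** two_h
    )


def estimate_m2(
    acvf: ACVFVector,
    config: M2Config | None = None,
    diffusion: float | None = 1.0,
) -> HurstEstimate:
    """Least-squares ACVF fit over H ∈ (0, 1), optionally joint in (H, D).

    With ``config.estimate_diffusion`` (or ``diffusion=None``) the diffusion
    coefficient is profiled out in closed form and lag 0 enters the
    objective; otherwise D is treated as known and the sum runs over lags
    1..τmax only.
    """
    config = config or M2Config()
    estimate_d = config.estimate_diffusion or diffusion is None
    include_lag0 = estimate_d if config.include_lag0 is None else config.include_lag0

    tau_lo = 0 if include_lag0 else 1
    if acvf.max_lag < config.tau_max:
        raise ValueError(
            f"ACVF covers lags 0..{acvf.max_lag}, need tau_max={config.tau_max}"
        )
    taus = np.arange(tau_lo, config.tau_max + 1, dtype=float)
    gamma_hat = acvf.values[tau_lo: config.tau_max + 1]

    if estimate_d:
        def objective(h: float) -> float:
            g = _unit_curve(taus, h)
            denom = g @ g
            d = max((gamma_hat @ g) / denom, 0.0) if denom > 0 else 0.0
            r = gamma_hat - d * g
            return r @ r
    else:
        d_known = float(diffusion)
        if d_known <= 0:
            raise ValueError("diffusion must be positive")

        def objective(h: float) -> float:
            r = gamma_hat - d_known * _unit_curve(taus, h)
            return r @ r

    # Bounded Brent refinement on each cell of an equal partition of (0, 1);
    # global best wins, ties (within 1e-12) go to the smaller H.
    edges = np.linspace(EPS_H, 1.0 - EPS_H, config.n_grid_starts + 1)
    best_h, best_obj = None, np.inf
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": config.tol},
        )
        h_cand, f_cand = float(res.x), float(res.fun)
        if f_cand < best_obj - 1e-12 or (
            abs(f_cand - best_obj) <= 1e-12 and (best_h is None or h_cand < best_h)
        ):
            best_h, best_obj = h_cand, f_cand

    d_hat = None
    if estimate_d:
        g = _unit_curve(taus, best_h)
        denom = g @ g
        d_hat = max(float((gamma_hat @ g) / denom), 0.0) if denom > 0 else 0.0
        if d_hat == 0.0:
            return HurstEstimate(hurst_hat=np.nan, method="M2", valid=False,
                                 diffusion_hat=0.0, objective=best_obj)

    h, clipped = _clip_h(best_h)
    return HurstEstimate(hurst_hat=h, method="M2", valid=True,
                         diffusion_hat=d_hat, objective=best_obj,
                         clipped=clipped, raw_hurst=best_h if clipped else None)
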