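"""Exact simulation of fractional Gaussian noise and fractional Brownian motion.

Fractional Brownian motion (FBM) is the centered, self-similar Gaussian
process with stationary increments, indexed by the Hurst exponent
``H ∈ (0, 1)`` and a diffusion coefficient ``D > 0``:

    Cov(X(t), X(s)) = (D/2) (t^{2H} + s^{2H} - |t - s|^{2H}),
    Var X(t) = D t^{2H}.

Its unit-step increment process, fractional Gaussian noise (fGn), is
stationary with autocovariance

    γ(τ) = (D/2) (|τ+1|^{2H} + |τ-1|^{2H} - 2 |τ|^{2H}).

Increments are positively correlated for H > 1/2 (superdiffusion,
long-range dependence), negatively correlated for H < 1/2 (subdiffusion),
and white for H = 1/2 (ordinary Brownian motion, where the anomalous
diffusion exponent α = 2H equals 1).

Simulation is exact: the n×n Toeplitz covariance of the fGn vector is
assembled from γ and factorized by Cholesky decomposition; multiplying the
lower factor by a seeded standard-normal draw yields an fGn sample with
exactly the target covariance for any H ∈ (0, 1), including values near the
endpoints where circulant-embedding generators can fail on short samples.
FBM trajectories are cumulative sums of fGn with the convention X(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "FGNParams",
    "Trajectory",
    "SimulationConditioningError",
    "theoretical_acvf_fgn",
    "fbm_covariance",
    "build_fgn_covariance",
    "cholesky_factor",
    "CholeskyCache",
    "sample_fgn",
    "simulate_fgn",
    "simulate_fgn_many",
    "simulate_fbm",
    "write_trajectories",
    "read_trajectories",
]


class SimulationConditioningError(RuntimeError):
    """Cholesky factorization of the fGn covariance failed even with jitter."""


def _check_domain(hurst: float, diffusion: float) -> None:
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie strictly in (0, 1); got {hurst}")
    if not diffusion > 0.0:
        raise ValueError(f"diffusion must be positive; got {diffusion}")


@dataclass(frozen=True)
class FGNParams:
    """Parameters of fractional Gaussian noise / fractional Brownian motion.

    Attributes
    ----------
    hurst : float
        Hurst exponent H, strictly inside (0, 1). The boundary values are the
        degenerate limits (fully antipersistent / ballistic) and are rejected.
    diffusion : float
        Diffusion coefficient D > 0, the variance scale at unit time
        (Var X(1) = D under a unit sampling interval).
    n_increments : int
        Number of increments n of the simulated trajectory; the trajectory
        itself has n + 1 points including X(0) = 0.
    """

    hurst: float
    diffusion: float = 1.0
    n_increments: int = 1

    def __post_init__(self) -> None:
        _check_domain(self.hurst, self.diffusion)
        if int(self.n_increments) != self.n_increments or self.n_increments < 1:
            raise ValueError(
                f"n_increments must be a positive integer; got {self.n_increments}"
            )

    @property
    def alpha(self) -> float:
        """Anomalous diffusion exponent α = 2H (E[X²(t)] ~ t^α)."""
        return 2.0 * self.hurst


@dataclass(frozen=True)
class Trajectory:
    """An FBM sample path on the integer grid 0, 1, ..., n with X(0) = 0."""

    positions: np.ndarray
    params: FGNParams
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 1 or pos.size != self.params.n_increments + 1:
            raise ValueError(
                "positions must be a vector of length n_increments + 1; "
                f"got shape {pos.shape} for n={self.params.n_increments}"
            )
        if pos[0] != 0.0:
            raise ValueError("positions[0] must be exactly 0 (X(0) = 0 convention)")

    def increments(self) -> np.ndarray:
        """The fGn increment series ξ(t) = X(t) − X(t−1), length n_increments."""
        return np.diff(self.positions)


def theoretical_acvf_fgn(tau, hurst: float, diffusion: float = 1.0):
    """Theoretical fGn autocovariance γ(τ) = (D/2)(|τ+1|^{2H} + |τ−1|^{2H} − 2|τ|^{2H}).

    ``tau`` may be a scalar or array of nonnegative lags; γ(0) = D, and for
    τ ≥ 1 the sign is that of H − 1/2.
    """
    _check_domain(hurst, diffusion)
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("lag tau must be nonnegative")
    two_h = 2.0 * hurst
    out = 0.5 * diffusion * (
        np.abs(tau_arr + 1.0) ** two_h
        + np.abs(tau_arr - 1.0) ** two_h
        - 2.0 * np.abs(tau_arr) ** two_h
    )
    return float(out) if np.isscalar(tau) or out.ndim == 0 else out


def fbm_covariance(t, s, hurst: float, diffusion: float = 1.0):
    """FBM covariance Cov(X(t), X(s)) = (D/2)(t^{2H} + s^{2H} − |t−s|^{2H})."""
    _check_domain(hurst, diffusion)
    t_arr = np.asarray(t, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if np.any(t_arr < 0) or np.any(s_arr < 0):
        raise ValueError("times must be nonnegative")
    two_h = 2.0 * hurst
    out = 0.5 * diffusion * (
        t_arr ** two_h + s_arr ** two_h - np.abs(t_arr - s_arr) ** two_h
    )
    # X(0) = 0 a.s.: exact zero on the axes, avoiding cancellation residue
    out = np.where((t_arr == 0.0) | (s_arr == 0.0), 0.0, out)
    return float(out) if out.ndim == 0 else out


def build_fgn_covariance(params: FGNParams) -> np.ndarray:
    """Symmetric Toeplitz covariance matrix of n consecutive fGn increments.

    Entry (i, j) is γ(|i − j|); the matrix is positive definite for every
    H ∈ (0, 1).
    """
    first_row = theoretical_acvf_fgn(
        np.arange(params.n_increments), params.hurst, params.diffusion
    )
    return toeplitz(np.atleast_1d(first_row))


def cholesky_factor(params: FGNParams) -> np.ndarray:
    """Lower Cholesky factor of the fGn covariance, with jittered retries.

    For H close to 1 and large n the Toeplitz covariance is badly
    conditioned; on factorization failure a diagonal jitter of
    1e-12 · trace/n is added and escalated tenfold, up to three retries.
    """
    cov = build_fgn_covariance(params)
    n = cov.shape[0]
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-12 * np.trace(cov) / n
    for _ in range(3):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise SimulationConditioningError(
        f"Cholesky factorization of the fGn covariance failed for "
        f"H={params.hurst}, n={n} even after jittered retries"
    )


class CholeskyCache:
    """Opt-in cache of Cholesky factors keyed by (hurst, n_increments, diffusion).

    Useful when simulating many trajectories at a fixed parameter set
    (Monte Carlo at fixed H); by default every trajectory recomputes its own
    factor, since in the benchmark protocol H changes per trajectory.
    """

    def __init__(self) -> None:
        self._factors: dict[tuple[float, int, float], np.ndarray] = {}

    def factor(self, params: FGNParams) -> np.ndarray:
        key = (params.hurst, params.n_increments, params.diffusion)
        if key not in self._factors:
            self._factors[key] = cholesky_factor(params)
        return self._factors[key]

    def __len__(self) -> int:
        return len(self._factors)


def sample_fgn(
    params: FGNParams,
    rng: np.random.Generator,
    factor: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one fGn vector of length n_increments from an existing generator."""
    if factor is None:
        factor = cholesky_factor(params)
    z = rng.standard_normal(params.n_increments)
    return factor @ z


def simulate_fgn(
    params: FGNParams, seed: int, cache: CholeskyCache | None = None
) -> np.ndarray:
    """Exact seeded simulation of an fGn vector (L·z, L the Cholesky factor)."""
    factor = cache.factor(params) if cache is not None else None
    return sample_fgn(params, np.random.default_rng(seed), factor=factor)


def simulate_fgn_many(
    params: FGNParams,
    n_reps: int,
    seed: int,
    cache: CholeskyCache | None = None,
) -> np.ndarray:
    """Simulate ``n_reps`` independent fGn vectors; returns shape (n_reps, n).

    Shares one Cholesky factor across replicates, so Monte Carlo studies at
    fixed parameters cost one factorization plus a matrix product.
    """
    factor = cache.factor(params) if cache is not None else cholesky_factor(params)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((params.n_increments, n_reps))
    return (factor @ z).T


def simulate_fbm(params: FGNParams, seed: int) -> Trajectory:
    """Simulate an FBM trajectory: X(0) = 0 prepended to the cumsum of fGn."""
    incr = simulate_fgn(params, seed)
    positions = np.concatenate(([0.0], np.cumsum(incr)))
    return Trajectory(positions=positions, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Plain-text trajectory files: one trajectory per row, a comment header
# recording the generating parameters. %.17g preserves doubles exactly.

def write_trajectories(
    path,
    positions: np.ndarray,
    params: FGNParams,
    seed: int | None = None,
) -> None:
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    header = (
        f"hurst={params.hurst!r} diffusion={params.diffusion!r} "
        f"n_increments={params.n_increments} seed={seed if seed is not None else 'none'}"
    )
    np.savetxt(path, pos, fmt="%.17g", header=header)


def read_trajectories(path) -> tuple[np.ndarray, FGNParams, int | None]:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
    fields = dict(item.split("=", 1) for item in header.split())
    params = FGNParams(
        hurst=float(fields["hurst"]),
        diffusion=float(fields["diffusion"]),
        n_increments=int(fields["n_increments"]),
    )
    seed = None if fields.get("seed", "none") == "none" else int(fields["seed"])
    positions = np.atleast_2d(np.loadtxt(path))
    return positions, params, seed
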