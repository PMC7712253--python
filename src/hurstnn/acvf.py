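"""Sample autocovariance of fGn increments and its model expectation.

The sample ACVF used throughout is the biased (divisor-n) estimator

    γ̂(τ) = (1/n) Σ_{t=1}^{n−τ} ξ(t) ξ(t+τ),   τ = 0, 1, ..., n−1,

chosen over the unbiased divisor-(n−τ) version for its lower variance. The
increments are not de-meaned by default: fGn is a centered process, and the
estimator is applied to raw products. Under the FBM model its expectation is
E[γ̂(τ)] = ((n−τ)/n) γ(τ), which `expected_sample_acvf` evaluates.

`restrict_lags` implements the lag-budget device used when probing how many
ACVF lags carry information: the first k lags are kept and the remainder are
reset to exactly zero, which makes the tail of the input indistinguishable
from the uncorrelated H = 1/2 case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fgn import theoretical_acvf_fgn

__all__ = [
    "ACVFVector",
    "sample_acvf",
    "theoretical_acvf_vector",
    "expected_sample_acvf",
    "restrict_lags",
    "write_acvf",
    "read_acvf",
]

_KINDS = ("sample", "theoretical", "zero_padded")


@dataclass(frozen=True)
class ACVFVector:
    """Autocovariance values indexed by lag 0..max_lag.

    ``n_source`` is the number of increments the values were computed from
    (or notionally correspond to, for theoretical vectors); ``kind`` tags the
    provenance: a sample estimate, an exact model evaluation, or a sample
    vector whose tail lags have been zeroed.
    """

    values: np.ndarray
    n_source: int
    kind: str = "sample"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a nonempty 1-D vector")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}; got {self.kind!r}")
        if self.n_source < 1:
            raise ValueError("n_source must be a positive integer")
        if self.kind == "sample":
            if vals[0] < 0:
                raise ValueError("sample ACVF at lag 0 is a mean of squares, must be >= 0")
            if vals.size - 1 > self.n_source - 1:
                raise ValueError("sample ACVF max_lag must be <= n_source - 1")

    @property
    def max_lag(self) -> int:
        return self.values.size - 1

    def __len__(self) -> int:
        return self.values.size


def sample_acvf(increments, max_lag: int | None = None, demean: bool = False) -> ACVFVector:
    """Biased sample ACVF γ̂(τ) = (1/n) Σ ξ(t)ξ(t+τ), divisor n at every lag.

    Parameters
    ----------
    increments : array-like, length n ≥ 1
    max_lag : int, optional
        Highest lag computed; defaults to n − 1. Must satisfy
        0 ≤ max_lag ≤ n − 1.
    demean : bool
        Subtract the sample mean first. Off by default (the model process is
        centered); provided for robustness on real recordings with drift.
    """
    x = np.asarray(increments, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("increments must be a nonempty 1-D vector")
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must satisfy 0 <= max_lag <= n - 1 = {n - 1}; got {max_lag}")
    if demean:
        x = x - x.mean()
    vals = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        vals[tau] = x[: n - tau] @ x[tau:]
    vals /= n
    return ACVFVector(values=vals, n_source=n, kind="sample")


def theoretical_acvf_vector(
    max_lag: int, hurst: float, diffusion: float = 1.0, n_source: int | None = None
) -> ACVFVector:
    """Exact model ACVF γ(τ) for τ = 0..max_lag, as an ACVFVector."""
    vals = theoretical_acvf_fgn(np.arange(max_lag + 1), hurst, diffusion)
    return ACVFVector(
        values=np.atleast_1d(vals),
        n_source=n_source if n_source is not None else max_lag + 1,
        kind="theoretical",
    )


def expected_sample_acvf(tau: int, n: int, hurst: float, diffusion: float = 1.0) -> float:
    """Expectation of the biased sample ACVF: ((n − τ)/n) γ(τ)."""
    if not 0 <= tau <= n - 1:
        raise ValueError(f"tau must satisfy 0 <= tau <= n - 1 = {n - 1}; got {tau}")
    return (n - tau) / n * theoretical_acvf_fgn(tau, hurst, diffusion)


def restrict_lags(acvf: ACVFVector, n_nonzero: int, target_len: int | None = None) -> ACVFVector:
    """Keep the first ``n_nonzero`` lags, reset the rest to exactly zero.

    The output has length ``target_len`` (default: the input length); zeroed
    tail lags mimic the uncorrelated-increment (H = 1/2) regime beyond the
    retained window.
    """
    if target_len is None:
        target_len = len(acvf)
    if not 1 <= n_nonzero <= target_len:
        raise ValueError(
            f"n_nonzero must satisfy 1 <= n_nonzero <= target_len = {target_len}; got {n_nonzero}"
        )
    if len(acvf) < n_nonzero:
        raise ValueError(
            f"input ACVF has only {len(acvf)} lags, cannot retain {n_nonzero}"
        )
    out = np.zeros(target_len)
    out[:n_nonzero] = acvf.values[:n_nonzero]
    return ACVFVector(values=out, n_source=acvf.n_source, kind="zero_padded")


def write_acvf(path, acvf: ACVFVector) -> None:
    np.savetxt(path, acvf.values, fmt="%.17g",
               header=f"n_source={acvf.n_source} kind={acvf.kind}")


def read_acvf(path) -> ACVFVector:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
    fields = dict(item.split("=", 1) for item in header.split())
    values = np.atleast_1d(np.loadtxt(path))
    return ACVFVector(values=values, n_source=int(fields["n_source"]), kind=fields["kind"])
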