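"""Seeded corpora of (32-lag sample ACVF, true H) pairs for training and testing.

Each example follows the simulation protocol of the benchmark study: a Hurst
exponent drawn uniformly on (0, 1), an fGn of the configured length simulated
exactly by Cholesky factorization, the biased sample ACVF computed over all
available lags, and the vector truncated to its first ``input_lags`` (32)
lags. Trajectory lengths are stratified: each length in the configured grid
contributes exactly its per-length count to every split.

Two scales are provided. ``full`` plans the full-size corpus — 262,144
training and 32,768 validation/test examples per length over lengths
{32, 64, 128, 256, 512, 1024}, i.e. 1,572,864 / 196,608 / 196,608 examples —
and is intended for planning/manifest purposes or long offline runs.
``reduced`` (the default constructor used throughout the test harness)
keeps the same protocol at 2,000 training and 500 evaluation examples per
length over lengths {32, 64, 128, 256}, which builds in seconds on one CPU.

Train/validation/test use disjoint child streams spawned from one seed, so
splits never share realizations and every corpus is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .acvf import sample_acvf
from .fgn import FGNParams, sample_fgn

__all__ = [
    "CorpusConfig",
    "LabeledACVF",
    "CorpusSplit",
    "make_example",
    "planned_counts",
    "manifest",
    "build_corpus",
    "save_corpus",
    "load_corpus",
]

FULL_LENGTHS = (32, 64, 128, 256, 512, 1024)
REDUCED_LENGTHS = (32, 64, 128, 256)


@dataclass(frozen=True)
class CorpusConfig:
    lengths: tuple[int, ...] = FULL_LENGTHS
    per_length_train: int = 262_144
    per_length_eval: int = 32_768
    diffusion: float = 1.0
    input_lags: int = 32
    seed: int = 0
    scale: str = "full"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", tuple(self.lengths))
        if any(n < self.input_lags for n in self.lengths):
            raise ValueError("every trajectory length must be >= input_lags")
        if self.per_length_train < 1 or self.per_length_eval < 1:
            raise ValueError("per-length counts must be >= 1")
        if self.scale not in ("full", "reduced"):
            raise ValueError("scale must be 'full' or 'reduced'")

    @classmethod
    def reduced(
        cls,
        lengths: tuple[int, ...] = REDUCED_LENGTHS,
        per_length_train: int = 2000,
        per_length_eval: int = 500,
        seed: int = 0,
        **kwargs,
    ) -> "CorpusConfig":
        return cls(lengths=lengths, per_length_train=per_length_train,
                   per_length_eval=per_length_eval, seed=seed,
                   scale="reduced", **kwargs)


@dataclass(frozen=True)
class LabeledACVF:
    """One training example: truncated sample ACVF with its generating H."""

    acvf32: np.ndarray
    hurst_true: float
    length: int
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "acvf32", np.asarray(self.acvf32, dtype=float))
        if not 0.0 < self.hurst_true < 1.0:
            raise ValueError("hurst_true must lie in (0, 1)")


@dataclass(frozen=True)
class CorpusSplit:
    """A split as flat arrays: inputs (m, input_lags), targets (m,), lengths (m,)."""

    inputs: np.ndarray
    targets: np.ndarray
    lengths: np.ndarray

    def __len__(self) -> int:
        return self.targets.size


def _draw_hurst(rng: np.random.Generator) -> float:
    # rejection of the measure-zero endpoints keeps H strictly inside (0, 1)
    while True:
        h = float(rng.uniform())
        if 0.0 < h < 1.0:
            return h


def make_example(
    length: int,
    diffusion: float = 1.0,
    rng: np.random.Generator | None = None,
    input_lags: int = 32,
    seed: int | None = None,
) -> LabeledACVF:
    """Generate one example: H ~ U(0, 1), exact fGn, biased ACVF, first 32 lags."""
    if length < input_lags:
        raise ValueError(f"length must be >= input_lags = {input_lags}")
    if rng is None:
        rng = np.random.default_rng(seed)
    h = _draw_hurst(rng)
    params = FGNParams(hurst=h, diffusion=diffusion, n_increments=length)
    incr = sample_fgn(params, rng)
    acvf = sample_acvf(incr, max_lag=length - 1)
    return LabeledACVF(acvf32=acvf.values[:input_lags], hurst_true=h,
                       length=length, seed=seed)


def planned_counts(config: CorpusConfig) -> dict[str, int]:
    """Split sizes implied by the configuration, without materializing data."""
    k = len(config.lengths)
    return {
        "train": config.per_length_train * k,
        "validation": config.per_length_eval * k,
        "test": config.per_length_eval * k,
    }


def manifest(config: CorpusConfig) -> dict:
    """Self-describing record of the corpus: configuration and planned counts."""
    return {
        "config": asdict(config),
        "planned_counts": planned_counts(config),
        "splits": ["train", "validation", "test"],
    }


def _materialize(
    config: CorpusConfig, per_length: int, rng: np.random.Generator
) -> CorpusSplit:
    total = per_length * len(config.lengths)
    inputs = np.empty((total, config.input_lags))
    targets = np.empty(total)
    lens = np.empty(total, dtype=int)
    row = 0
    for length in config.lengths:
        for _ in range(per_length):
            ex = make_example(length, config.diffusion, rng,
                              input_lags=config.input_lags)
            inputs[row] = ex.acvf32
            targets[row] = ex.hurst_true
            lens[row] = length
            row += 1
    return CorpusSplit(inputs=inputs, targets=targets, lengths=lens)


def build_corpus(
    config: CorpusConfig,
) -> tuple[CorpusSplit, CorpusSplit, CorpusSplit, dict]:
    """Materialize train/validation/test splits from disjoint seeded streams."""
    train_ss, val_ss, test_ss = np.random.SeedSequence(config.seed).spawn(3)
    train = _materialize(config, config.per_length_train, np.random.default_rng(train_ss))
    val = _materialize(config, config.per_length_eval, np.random.default_rng(val_ss))
    test = _materialize(config, config.per_length_eval, np.random.default_rng(test_ss))
    info = manifest(config)
    info["realized_counts"] = {
        "train": len(train), "validation": len(val), "test": len(test)
    }
    return train, val, test, info


def save_corpus(out_dir, train: CorpusSplit, val: CorpusSplit,
                test: CorpusSplit, info: dict) -> None:
    """Write the three splits as a flat array archive plus a JSON manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, split in (("train", train), ("validation", val), ("test", test)):
        np.savez(out / f"{name}.npz", inputs=split.inputs,
                 targets=split.targets, lengths=split.lengths)
    with open(out / "manifest.json", "w") as fh:
        json.dump(info, fh, indent=2)


def load_corpus(out_dir) -> tuple[CorpusSplit, CorpusSplit, CorpusSplit, dict]:
    from pathlib import Path

    out = Path(out_dir)
    splits = []
    for name in ("train", "validation", "test"):
        with np.load(out / f"{name}.npz") as arr:
            splits.append(CorpusSplit(inputs=arr["inputs"], targets=arr["targets"],
                                      lengths=arr["lengths"]))
    with open(out / "manifest.json") as fh:
        info = json.load(fh)
    return splits[0], splits[1], splits[2], info
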