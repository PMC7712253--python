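# hurstnn

Hurst exponent estimation for fractional Brownian motion from the sample
autocovariance function — for researchers analyzing anomalous diffusion in
single-particle tracking and similar equally-sampled scalar trajectories,
where the central question is whether motion is subdiffusive, diffusive, or
superdiffusive, and trajectories are often too short for asymptotic
statistics to behave.

## The problem and the methods

Fractional Brownian motion (FBM) is the centered self-similar Gaussian
process with stationary increments, indexed by the Hurst exponent
`H ∈ (0, 1)` (anomalous diffusion exponent `α = 2H`) and diffusion
coefficient `D`:

    Cov(X(t), X(s)) = (D/2)(t^{2H} + s^{2H} − |t − s|^{2H})

Its increments — fractional Gaussian noise — have autocovariance
`γ(τ) = (D/2)(|τ+1|^{2H} + |τ−1|^{2H} − 2|τ|^{2H})`, which completely
determines the process. All three estimators here read the biased
(divisor-n) sample ACVF `γ̂(τ) = (1/n) Σ_t ξ(t)ξ(t+τ)` of the increment
series:

- **M1** — closed-form inversion of the lag-1 value:
  `Ĥ = ½ log₂(2γ̂(1)/D + 2)`.
- **M2** — nonlinear least-squares fit of the γ curve over lags 1..τmax
  (default 31), with `D` known or profiled out jointly.
- **M3** — a feedforward network 32→64→64→32→1 (Swish-1 hidden layers,
  sigmoid output, 8385 parameters) mapping the first 32 ACVF lags to `Ĥ`,
  trained with Adam/MSE and early stopping on simulated FBM with
  `H ~ U(0, 1)`.

The package also provides the exact Cholesky-based fGn/FBM simulator
(exact for every `H`, including near 1), the seeded corpus builder, and a
Monte Carlo benchmark harness that compares the methods by mean absolute
error across trajectory lengths and true-`H` bins. See `docs/methods.md`
for the full model and design notes.

## Worked example

```python
import numpy as np
import hurstnn as hn

# simulate a superdiffusive trajectory: H = 0.7, D = 1, 256 increments
params = hn.FGNParams(hurst=0.7, diffusion=1.0, n_increments=256)
traj = hn.simulate_fbm(params, seed=42)
acvf = hn.sample_acvf(traj.increments(), max_lag=31)

m1 = hn.estimate_m1(acvf, diffusion=1.0)
m2 = hn.estimate_m2(acvf, hn.M2Config(tau_max=31), diffusion=1.0)
print(f"M1: {m1.hurst_hat:.4f}  M2: {m2.hurst_hat:.4f}")
```

```
M1: 0.6968  M2: 0.6260
```

Both classical estimators land near the true `H = 0.7`: the lag-1
inversion uses a single statistic, while the least-squares fit pools 31
lags (the distant ones contributing mostly noise on a single trajectory).
Training and applying the network estimator:

```python
cfg = hn.CorpusConfig.reduced(seed=0)          # 2000 train / 500 eval per length
train, val, test, _ = hn.build_corpus(cfg)      # lengths 32..256, H ~ U(0,1)
model = hn.train(hn.build_model(seed=0),
                 (train.inputs, train.targets),
                 (val.inputs, val.targets))
m3 = hn.estimate_m3(acvf.values[:32], model)
err = np.abs(model.predict(test.inputs) - test.targets)
print(f"M3: {m3.hurst_hat:.4f}   held-out test MAE: {err.mean():.4f}")
```

```
M3: 0.7092   held-out test MAE: 0.0442
```

The held-out MAE of ~0.05 means the network recovers `H` to within about
0.05 on average over the whole (0, 1) range at these trajectory lengths;
the benchmark (`hn.run_benchmark`) breaks this down by length and true-`H`
bin, where M3's advantage concentrates in the strongly sub- and
superdiffusive regimes on short trajectories.

A command-line interface wraps the same pipeline:

```bash
hurstnn simulate --hurst 0.7 --n 256 --reps 10 --seed 1 --out traj.txt
hurstnn estimate --method m2 --in traj.txt
hurstnn build-dataset --scale reduced --seed 0 --out-dir corpus/
hurstnn train --corpus-dir corpus/ --out model.json
hurstnn benchmark --methods m1,m2,m3 --model model.json --out-dir bench/
```

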