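# copsep

Blind separation of fetal and maternal ECG from noisy two-channel
abdominal recordings, via bilateral total-variation denoising and
copula-based Kullback–Leibler minimization.

## The problem

Cutaneous electrodes on a pregnant woman's abdomen record mixtures of
the maternal ECG (MECG), the much weaker and faster fetal ECG (FECG),
and noise.  With two electrodes and instantaneous mixing the
observation model is

```
x̄(t) = A s(t) + n(t)
```

where `s = (s_MECG, s_FECG)` are the unknown sources, `A` is an unknown
nonsingular 2×2 mixing matrix and `n` is centered Gaussian noise.  The
goal is to recover `s` up to per-channel scale and permutation — a noisy
blind source separation (BSS) problem.  Classical independence-based
BSS (ICA) breaks down when the two cardiac sources are statistically
dependent (e.g. coincident beats); the method implemented here handles
both the independent and the dependent case.

## The method

**Stage 1 — denoising.**  Each observed channel is cleaned by
minimizing a quadratic-fidelity + bilateral total-variation objective

```
min_x  ½‖x − x̄‖² + λ Σ_{j=−m..m} α^|j| ‖x − G^j x‖₁
```

where `G^j` shifts the signal by `j` samples.  The nonsmooth convex
problem is solved by a first-order primal–dual (Chambolle–Pock) scheme
with the strongly-convex acceleration, auto-tuned step sizes and an
exact adjoint pair for the stacked difference operator
(`copsep.btv_denoise`).

**Stage 2 — separation.**  The demixing matrix `B` is estimated by
minimizing the modified Kullback–Leibler divergence between a reference
copula density `c_ref` and the kernel-estimated copula density of the
outputs `Y = B X`:

```
KL_m(c_ref, c_Y) ≈ (1/N) Σ_n log[ ĉ_Y(Û(n)) / c_ref(Û(n)) ]
```

with `Û(n)` the pseudo-observations of the outputs (Gaussian-smoothed
marginal CDFs evaluated at the samples), `ĉ_Y` a product-Gaussian
kernel copula density with Silverman rule-of-thumb bandwidths and
mirror-reflection boundary correction (`copsep.nonparam_estimation`),
and `c_ref` either the product copula (independent sources) or a
parametric Ali–Mikhail–Haq / Clayton copula (dependent sources,
`copsep.copula_models`).  The criterion is minimized by projected
gradient descent from `B₀ = I` on the unit-row-norm manifold with
backtracking line search and a per-row exact line-search refinement
(`copsep.bss_separation`).  Separation quality is measured after
correlation-based channel alignment by the per-channel SNR
`10·log10(Σ s² / Σ (y − s)²)` and the Amari index of `B̂A`
(`copsep.metrics_io`).

A synthetic-data module (`copsep.simulate`) generates the benchmark:
quasi-periodic PQRST beat trains (maternal ≈ 85 bpm, unit amplitude;
fetal ≈ 140 bpm, amplitude 0.25), optional copula coupling of the two
sources by rank remapping, mixing with `A = [[1, 0.8], [0.8, 1]]`,
per-channel unit max-abs normalization and Gaussian noise with
σ = 0.1.

## Worked example

```python
import numpy as np
from copsep import ExperimentConfig, run_experiment

rep = run_experiment(ExperimentConfig(case="independent", seed=101))
print("mean SNR (dB):        %.2f" % rep.mean_snr_db)
print("per-channel SNR (dB): %s" % np.round(rep.per_channel_snr_db, 2))
print("final KL criterion:   %.4f" % rep.final_criterion)
print("final Kendall tau:    %.4f" % rep.final_tau)
print("Amari index:          %.4f" % rep.amari)
```

prints

```
mean SNR (dB):        5.62
per-channel SNR (dB): [11.04  0.21]
final KL criterion:   0.0674
final Kendall tau:    -0.0107
Amari index:          0.3084
```

The run simulates one independent-source mixture at the default study
conditions (N = 2500 samples at 250 Hz, σ = 0.1), grid-tunes the
denoiser weight λ against the known clean mixtures, separates with the
product-copula criterion and aligns the estimates to the true sources.
The Kendall tau of the separated outputs collapses to ≈ 0 (the
separation criterion has done its job on the rank structure), while the
absolute SNR is limited by the residual noise that the denoiser cannot
remove and by the 4:1 maternal-to-fetal amplitude ratio — the weak
fetal channel pays the price of noise amplification through the
demixing matrix.  See `docs/methods.md` for the quantitative anatomy of
this error budget.

The same pipeline is available from the shell:

```sh
copsep simulate --case independent --n 2500 --sigma 0.1 --seed 7 \
    --out sources.csv mixtures.csv
copsep denoise --input mixtures.csv --lambda 0.05 --output denoised.csv
copsep separate --input denoised.csv --copula product --output estimated.csv \
    --trace trace.csv
copsep run --config experiment.yaml --outdir results/
```

For dependent sources, pass `--case clayton --theta 0.5` (or `amh`,
θ = 0.4) to `simulate` and the matching `--copula`/`--theta` to
`separate`.

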