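# ddehm — hybrid delay-differential-equation modelling of biochemical networks

Biochemical networks are full of intrinsic time delays — transcription,
translation, maturation and transport all take time, and at the process
level the lag between substrate uptake and growth or product formation
is plainly visible in bioreactor data.  The mechanisms behind these
delays are usually unknown, so they cannot be written down as
first-principles kinetics.  `ddehm` implements a hybrid semi-parametric
answer: keep the part of the model that *is* known — the material
balances — and let a small neural network learn the unknown kinetic
rates from **discrete time-lagged** state and input values.  The result
is a delay differential equation (DDE) whose nonparametric part can be
identified from ordinary concentration time series, and whose lag
structure, scanned over a grid, identifies the system's delay itself.

## The model

States `c` follow a material balance with a stoichiometric matrix `K`,
dilution `D` and volumetric inputs `u`:

    dc/dt = K · r(X, w) − D·c + u,        r(X, w) = ψ(X) ⊙ ρ(X, w)

`ψ` carries whatever parametric kinetics are known (possibly ≡ 1) and
`ρ` is a three-layer perceptron with hyperbolic-tangent hidden units fed
with the lagged input vector

    X = [cᵢ(t), cᵢ(t−τᵢ), …, cᵢ(t−Nᵢ·τᵢ), sⱼ(t), sⱼ(t−τⱼ), …]

(lagged values before t₀ clamp to the initial state).  The weights `w`
minimize the weighted least squares of the measured concentrations,

    E = 1/(P·n) Σₗ Σᵢ (c_m,l,i − c_l,i(t, w))² / c_σ,i ,

with gradients obtained *exactly* by integrating the forward sensitivity
equations d/dt(∂c/∂w) alongside the model — never by finite differences.
Training stops early at the iterate with the best validation criterion,
restarts from several random initializations, and structures
(hidden-node count × delay set) are compared by the Bayesian information
criterion on the validation split,

    BIC = −(n·P/2)·ln SSE − (n_w/2)·ln(n·P/(2π)),      larger is better.

Two complete synthetic case studies are included as first-class
simulators: a transcription-factor (TF-A) positive-feedback loop with a
120-min nuclear-translocation delay (discrete delay), and a fed-batch
*Pichia pastoris* culture where growth and product formation lag
methanol uptake through an Erlang-2 distributed-delay kernel (realized
by the linear chain trick, with a convolution-quadrature oracle to prove
the equivalence).

## Worked example

Generate the TF-A case study (three clean trajectories with different
initial concentrations, each corrupted twice with 5% white noise → six
datasets, two per train/validation/test role), then identify the
structure with 5 hidden nodes and a single 120-min input delay:

```python
import numpy as np
from ddehm import (make_case_study, configure_tfa, fit_multistart,
                   TrainOptions, criteria)

datasets = make_case_study("tfa", master_seed=1)
spec = configure_tfa("1C", hidden=5)            # 1 lag of 120 min + time input
opts = TrainOptions(step=1.0, max_iter=100)
fit = fit_multistart(spec, datasets["train"], datasets["valid"],
                     n_restarts=5, base_seed=1, opts=opts)
test = criteria(spec, fit.params, datasets["test"], opts)
print(f"selected restart seed {fit.seed}, stopped at iterate {fit.best_iter}")
print(f"validation BIC {fit.criteria['valid']['BIC']:.1f}")
print(f"test MSE {test['MSE']:.4f}")
```

prints

```
selected restart seed 1605295534, stopped at iterate 36
validation BIC -90.6
test MSE 0.0135
```

The test MSE of 0.0135 is the mean squared prediction error on the two
held-out runs — close to the 5%-noise floor of the data.  The same
structure *without* the 120-min lag fits about four times worse (test
MSE ≈ 0.05): the non-delayed model cannot reproduce the staircase
transition the translocation delay imprints on the trajectory.  Scanning
single delays {0, 100, 110, 120, 130, 140, 160} min and picking the row
with maximal validation BIC recovers the generating 120-min delay:

```
ddehm simulate --case tfa --seed 1 --out data/
ddehm gridsearch --model model.yaml --data data/ \
      --nodes 4,5,6 --delays "0;100;110;120;130;140;160" \
      --restarts 5 --seed 1 --out table.csv
```

The CLI (`ddehm simulate | train | gridsearch | evaluate | report |
pipeline`) is a thin layer over the library; every random draw descends
from the given master seed through named substreams, so all outputs are
bit-reproducible.

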