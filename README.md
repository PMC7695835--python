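# bindkin

Receptor–ligand binding kinetics and equilibrium pharmacology for
competition assays read in real time (e.g. NanoBRET tracer displacement at
a GPCR), plus the routine endpoint analyses that accompany an antagonist
characterisation campaign: logistic dose–response fits, Schild analysis,
Cheng–Prusoff affinity conversion, saturation binding and
substrate-depletion stability pharmacokinetics.

It is written for pharmacologists who fit plate-reader time courses: the
library exposes the closed-form models, the fitting workflow and the model
selection test directly, and a small CLI (`bindkin`) wraps them for shell
use.

## The models

Tracer `L` and unlabelled competitor `I` bind one receptor site reversibly
and mutually exclusively (`R + L ⇌ RL` with rates `k1, k2`; `R + I ⇌ RI`
with `k3, k4`), with ligand in excess. Specific tracer binding after
simultaneous addition follows the bi-exponential Motulsky–Mahan solution

    [RL]_t = N[L]k1/(K_F−K_S) · [ k4(K_F−K_S)/(K_F K_S)
                                  − (k4−K_S)/K_S · e^{−K_S t}
                                  + (k4−K_F)/K_F · e^{−K_F t} ]

with `K_F, K_S = ½{K_A + K_B ± √((K_A−K_B)² + 4[L][I]k1k3)}`,
`K_A = [L]k1 + k2`, `K_B = [I]k3 + k4`. When the competitor dissociates
too fast for `k4` to be resolved, it equilibrates essentially instantly
with free receptor and the trace collapses to the rapid-competitor limit

    [RL]_t = N[L]k1(1−ρ_I)/k_obs,+I · (1 − e^{−k_obs,+I t}),
    ρ_I = [I]/(K_I+[I]),   k_obs,+I = [L]k1(1−ρ_I) + k2,

which estimates only the equilibrium affinity `K_I`. The two fits are
compared by an extra-sum-of-squares partial F-test; the full model's extra
rate parameter is kept only when it significantly improves the fit.
Derived quantities: `K_D = k2/k1`, `K_i = k4/k3`, residence time
`RT = 1/k_off`, dissociation half-life `ln2/k_off`.

Endpoint analyses: 3-parameter logistic (unit Hill slope) fits, dose
ratios `DR = 10^{pEC50_ctrl − pEC50_antag}`, Schild regression of
`log(DR−1)` on `log[B]` (slope, pA2; pKB with slope constrained to unity),
saturation `B = Bmax[L]/(K_D+[L])`, Cheng–Prusoff
`K_i = IC50/(1+[L]/K_D)`, and first-order depletion half-lives with
intrinsic clearance `CL_int = ln2/(t_1/2 · mg protein/µl)`.

## Worked example

Fit a slow-dissociating antagonist's kinetics from a simulated competition
plate (tracer 5 nM, `k1 = 2.86e7 M⁻¹min⁻¹`, `k2 = 0.4397 min⁻¹`):

```python
import numpy as np
from bindkin import TracerKinetics, CompetitorKinetics, fit_competition_auto
from bindkin.synthetic import NoiseModel, gen_competition_plate, mrs1220_fixture

tracer, competitor, design = mrs1220_fixture()
traces, truth = gen_competition_plate(tracer, competitor, design,
                                      NoiseModel(sd_abs=0.005, seed=1))
traces = [t for t in traces if not t.meta["is_nsb"]]
fit, ftest = fit_competition_auto(traces, tracer)
print(f"selected: {ftest.selected}  (F={ftest.f_stat:.1f}, p={ftest.p_value:.2g})")
print(f"k3 = {fit.k3:.3g} M^-1 min^-1, k4 = {fit.k4:.4g} min^-1")
print(f"pKi = {fit.pKi:.2f}, residence time = {fit.residence_time:.1f} min")
```

prints

```
selected: motulsky_mahan  (F=1073.2, p=2.7e-62)
k3 = 3.22e+08 M^-1 min^-1, k4 = 0.02413 min^-1
pKi = 10.13, residence time = 41.4 min
```

i.e. the F-test keeps the full kinetic model (the competitor's off-rate is
resolvable), and the recovered rates reproduce the generating values
(`k3 = 3.25e8`, `k4 = 0.0248`, residence time 40.3 min, pKi 10.12) within
noise.
The same workflow on a fast-dissociating compound selects the rapid model
and reports only `pKi`.

From the shell:

```sh
bindkin simulate --seed 1 --noise-sd 0.005 --out plate.csv
bindkin fit-competition plate.csv --model auto --k1 2.86e7 --k2 0.4397
bindkin cheng-prusoff --ic50 322.6nM --tracer-conc 100nM --tracer-kd 102nM
```

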