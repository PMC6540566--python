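# groupedscore

Genome-wide association scans for **grouped failure-time phenotypes** —
time- or dose-to-event outcomes observed only up to membership in one of a
few pre-specified intervals (treatment cycles, dose steps, assessment
windows). Examples: cumulative number of chemotherapy cycles to the first
grade ≥ 2 neuropathy event, or the dose step at which a cytotoxicity
threshold is crossed. Treating such outcomes as heavily tied continuous
survival times (Efron/Breslow corrections in a Cox model) can bias effect
estimates; `groupedscore` instead uses the likelihood that matches the
observation process.

## Model and statistic

With intervals `[t_{j-1}, t_j)`, `j = 1..r` (`t_0 = 0`, `t_r = ∞`), a
proportional-hazards model `λ(t|x,z) = λ0(t) exp(xβ + zᵀθ)` induces the
grouped likelihood

    L_i = (1 − α_{k_i}^{w_i})^{δ_i} · ∏_{j<k_i} α_j^{w_i},
    w_i = exp(x_i β + z_iᵀ θ),

where `α_j = exp(−∫ λ0)` is the baseline probability of surviving interval
`j`, `k_i` the interval of the observed outcome and `δ_i` the event flag.
Each variant `x` is tested with the **efficient score statistic**

    W = (Σ_i S_β(0, η̂))² / [ n (Ī_ββ − Ī_βη Ī_ηη⁻¹ Ī_βηᵀ) ]  ~  χ²(1),

where `η̂ = (α̂, θ̂)` is the null MLE of the nuisance parameters, fitted
**once** and reused for every variant — that single fit is what makes a
scan of 10⁵–10⁶ variants cheap. The package also provides per-variant MLEs
`β̂` with standard errors, Bonferroni FWER adjustment, Storey q-values,
SKAT-type gene/pathway statistics built from per-sample score
contributions, and a simulator with censoring calibrated to a target event
rate.

## Worked example

```python
import numpy as np
from groupedscore import (SimulationConfig, simulate_grouped, fit_null,
                          NullScoreEngine, estimate_beta)

cfg = SimulationConfig(n=1000, beta=0.4, maf=0.3, target_event_rate=0.6, seed=2)
data, x, extras = simulate_grouped(cfg)          # 6-cycle design, 2 covariates
eta = fit_null(data)                             # null MLE of (alpha, theta)
res = NullScoreEngine(data, eta).test(x)
bh, se, _ = estimate_beta(data, x, eta)
print(f"event rate {data.delta.mean():.3f}")
print(f"W = {res['stat']:.2f}, p = {res['pvalue']:.2e}")
print(f"beta_hat = {bh:.3f} (se {se:.3f})")
```

prints

```
event rate 0.608
W = 19.93, p = 8.02e-06
beta_hat = 0.339 (se 0.076)
```

The simulated cohort hits the requested event rate, the score test flags
the true association, and the joint MLE recovers the simulated log hazard
ratio (0.4) within one standard error.

The same pipeline is available from the shell:

```sh
groupedscore simulate --n 1000 --m-variants 100 --event-rate 0.6 --out sim
groupedscore scan --pheno sim.pheno.tsv --covar sim.covar.tsv \
                  --geno sim.geno.tsv --beta-est --out run
```

which writes `run.variants.tsv` (columns `variant_id, n, maf, stat,
pvalue, fwer_p, qvalue, beta_hat, status`) and a plain-text QQ table.
`groupedscore opchar` runs type-I-error/power/bias grids and `groupedscore
genestat` aggregates saved per-sample contributions into gene-set
statistics.

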