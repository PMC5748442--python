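# treolss

Population pharmacokinetics of treosulfan and limited sampling strategies
(LSS) for estimating drug exposure in children conditioned for
hematopoietic stem cell transplantation.

High-dose treosulfan (10-14 g/m² infused over 1-2 h) is dosed by body
surface area, but exposure — the area under the concentration-time curve,
AUC₀→∞ — varies several-fold between children. Estimating AUC₀→∞ normally
needs ~10 blood samples per patient; a limited sampling strategy predicts
it from just 2-3 well-chosen samples. This package implements the full
pipeline for building and validating such strategies on top of a
population pharmacokinetic model:

* a **two-compartment IV-infusion model** with allometric bodyweight
  scaling referenced to 70 kg (θᵢ = θ·(BW/70)^β·e^η, β = 0.75 for
  clearance, 1 for volumes), log-normal interindividual variability on
  Cl, V₁ and Q with corr(η_Cl, η_V1), and proportional residual error —
  the fitted pediatric estimates ship as the packaged default model;
* a **virtual pediatric cohort simulator** (truncated-normal bodyweights,
  BSA-based dosing in three groups: 12 g/m²-1 h, 12 g/m²-2 h, 14 g/m²-2 h,
  a 10-time candidate sampling grid, LOQ censoring);
* **non-compartmental AUC₀→∞** by linear-up/log-down interpolation with
  best-adjusted-R² terminal-slope selection;
* **regression LSS development**: exhaustive search over admissible 2-/3-
  point time sets, OLS of AUC on concentrations, learning/validation
  split, Sheiner-Beal prediction-error metrics (MPE, MAPE, RMSE, ±20 %
  exceedances);
* **Bayesian (MAP or posterior-mean) individual estimation** of AUC from
  sparse samples with the population model fixed;
* an **NLME fitting engine** (SAEM with MCMC E-step; importance-sampled
  marginal likelihood; LRT/AIC/BIC model comparison with the 10.8 / 6.67
  MOFV thresholds; η-shrinkage; subject-level bootstrap; prediction-
  corrected VPC).

## Worked example

Develop and validate strategies for the 12 g/m², 2-h-infusion group
(100 virtual patients, fixed seed):

```python
import treolss as t
from treolss.workflow import develop_group

pop = t.final_model()                     # packaged pediatric estimates
g = develop_group(pop, "12g-2h", 12.0, 2.0, n=100, seed=1)
for k, ev in sorted(g.best.items()):
    m, r, b = ev.model, ev.regression, ev.bayesian
    eq = " + ".join(f"{c:.2f}*C{tt:g}h" for c, tt in zip(m.coefficients, m.times))
    print(f"{k}-point  AUCpred = {eq} + {m.intercept:.2f}   adjR2={m.adj_r2:.4f}")
    print(f"   regression validation: MPE {r.mpe:+.2f} %  MAPE {r.mape:.2f} %  RMSE {r.rmse:.2f} %")
    print(f"   Bayesian (all 100):    MPE {b.mpe:+.2f} %  MAPE {b.mape:.2f} %  RMSE {b.rmse:.2f} %")
```

prints

```
2-point  AUCpred = 2.02*C2h + 7.90*C6h + 40.67   adjR2=0.9925
   regression validation: MPE -0.15 %  MAPE 1.31 %  RMSE 1.57 %
   Bayesian (all 100):    MPE -1.53 %  MAPE 4.84 %  RMSE 5.98 %
3-point  AUCpred = 1.99*C2h + 2.09*C4h + 7.99*C8h + 0.78   adjR2=0.9991
   regression validation: MPE -0.13 %  MAPE 0.47 %  RMSE 0.59 %
   Bayesian (all 100):    MPE -1.71 %  MAPE 4.23 %  RMSE 5.29 %
```

Read: sampling at 2 h and 6 h after the start of a 2-h infusion, the
equation `AUC = 2.02·C₂ₕ + 7.90·C₆ₕ + 40.7` (mg·h/L with concentrations
in mg/L) explains 99.3 % of the exposure variance and predicts held-out
subjects with ~1.3 % mean absolute error; Bayesian estimation from the
same two samples is unbiased but noticeably more variable — both
behaviours expected for this design. The same machinery runs from the
shell:

```bash
treolss simulate --group 12g-2h --n 100 --seed 1 --out results/sim
treolss lss-develop --seed 1 --out results/lss     # all groups, 12 rows
treolss fit --data results/sim/dataset.csv --out results/fit
treolss vpc --data results/sim/dataset.csv --out results/vpc
```

Every command writes CSV results plus a `provenance.json` (config hash,
seeds, version) and is byte-reproducible under a fixed seed.

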