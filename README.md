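# cauticost

Hospital-level cost estimation for **catheter-associated urinary tract
infection (CAUTI)** — current annual costs, projected costs after an
intervention that reduces catheter placement and duration, and projected
savings, each with delta-method uncertainty and log-scale 95% confidence
intervals. It is aimed at infection-control professionals and hospital
epidemiologists who need a defensible dollar figure to make the business
case for catheter-reduction programs.

## The model

With `N` annual admissions, proportion catheterized `p`, bacteriuria risk
among the catheterized `R`, conditional SUTI and BSI risks `q_S`, `q_B`
(BSI conservatively assumed preceded by SUTI, so `q_B ≤ q_S`) and
per-patient costs `c_S`, `c_B`:

```
cost = c_S · N p R (q_S − q_B) + c_B · N p R q_B
```

An intervention reduces placement by a fraction `f_p` (scales `p`) and mean
catheterization duration by `f_d`, which lowers the bacteriuria risk via
the competing constant-hazard closed form

```
R' = (1 − f_d) R / (1 − f_d R)
```

Savings = current cost − post-intervention cost. Uncertainty in the five
literature inputs (`R`, `q_S`, `q_B`, `c_S`, `c_B`; all treated as
independent) propagates by the delta method,
`Var(T) ≈ Σ (∂T/∂θ_i)² SE_i²`, and intervals are multiplicatively
symmetric: `point · exp(±z · SE/point)`. A patient-level microsimulator
(Bernoulli placement, exponential duration, constant bacteriuria hazard,
nested SUTI/BSI events) provides an independent brute-force check of every
closed form. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

A hypothetical hospital with 3000 annual admissions and 15% of patients
catheterized (450 catheterized patients), using the packaged literature
defaults, under an intervention achieving the 29% placement and 37%
duration reductions seen in practice:

```sh
cauticost estimate --admissions 3000 --prop-catheterized 0.15 \
    --placement-reduction 0.29 --duration-reduction 0.37
```

prints

```
CAUTI cost estimate
===================
admissions:            3,000
proportion catheterized: 15.0%
placement reduction:   29.0%
duration reduction:    37.0%

current annual cost:   $37,850  (SE $27,499; 95% CI $9,113 – $157,213)
projected annual cost: $18,733  (SE $13,620; 95% CI $4,505 – $77,888)
projected savings:     $19,118  (SE $13,881; 95% CI $4,607 – $79,333)
savings fraction:      50.5%
```

The hospital currently spends about $37.9k per year on CAUTI; the
intervention is projected to cut that roughly in half (50.5%), saving about
$19.1k annually. The wide intervals reflect the large standard errors of
the literature cost inputs (SE equal to the mean), so point estimates
should be read as order-of-magnitude planning figures.

Equivalent library call:

```python
from cauticost import (HospitalScenario, RiskParams, CostParams,
                       Intervention, estimate_with_ci)

scen = HospitalScenario(admissions=3000, prop_catheterized=0.15)
iv = Intervention(placement_reduction=0.29, duration_reduction=0.37)
est = estimate_with_ci(scen, RiskParams(), CostParams(), iv, quantity="savings")
print(est.point, est.ci_low, est.ci_high)
# 19117.86 4607.06 79333.18
```

Other subcommands: `cauticost grid` evaluates savings with CIs over a
placement × duration reduction grid (CSV/JSON, optional heatmap);
`cauticost simulate` generates a seeded synthetic patient cohort with
per-patient trajectory records and a summary. Inputs can also come from a
flat YAML/JSON config file via `--config` (flags win); only `admissions`
and `prop_catheterized` are required, all risk/cost keys default to the
packaged literature values.

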