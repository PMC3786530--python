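# Methods

## The model

`cauticost` estimates a hospital's annual costs attributable to
catheter-associated urinary tract infection (CAUTI) from a small set of
hospital-level inputs, and projects the savings from interventions that
reduce urinary catheter use. Patients follow one of five trajectories after
catheter placement: no infection; asymptomatic bacteriuria only;
bacteriuria plus symptomatic UTI (SUTI); bacteriuria plus bloodstream
infection (BSI); or bacteriuria, SUTI and BSI. Two simplifying assumptions
make the accounting tractable and conservative:

1. Asymptomatic bacteriuria is costless (its presence is typically
   unknown), so only SUTI and BSI trajectories carry cost.
2. Patients with both SUTI and BSI incur the BSI cost only, and SUTI is
   assumed to precede BSI (the joint risk is not separately identified), so
   the conditional BSI risk is nested within the SUTI risk and
   `q_B <= q_S`.

With `N` annual admissions, proportion catheterized `p`, overall
bacteriuria risk among the catheterized `R`, conditional risks `q_S`
(SUTI | bacteriuria) and `q_B` (BSI | bacteriuria), and per-patient costs
`c_S` and `c_B`, the expected annual cost is

```
cost = c_S · N p R (q_S − q_B)  +  c_B · N p R q_B
```

Expected counts are kept real-valued throughout; rounding to whole patients
or dollars happens only in display formatting.

## Interventions and the duration-reduction closed form

An intervention is a pair of fractional reductions: `f_p` off the
proportion catheterized, and `f_d` off the mean catheterization duration
`d`. Placement reduction scales `p` directly. Duration reduction changes
the bacteriuria risk through a competing constant-hazard argument: if
bacteriuria arrives with constant hazard `λ_b` and the catheter is removed
with constant hazard `λ_r = 1/d`, then `R = λ_b/(λ_b + λ_r)`, i.e. the odds
`R/(1−R) = λ_b·d`. Scaling `d` by `(1−f_d)` therefore scales the odds by
`(1−f_d)`, giving

```
R' = (1 − f_d) R / (1 − f_d R)
```

which is monotone nonincreasing in `f_d`, with `R'(0) = R` and `R'(1) = 0`.
A discrete-time alternative, `R' = 1 − (1−R)^(1−f_d)`, was considered and
rejected: it disagrees with the continuous-time form by about 3% at
`f_d = 0.4` and does not reproduce the published savings figures, whereas
the odds-scaling form reproduces them within 0.1%. Savings are current cost
minus post-intervention cost; the conditional risks `q_S`, `q_B` and the
per-patient costs are held fixed across intervention.

The per-day bacteriuria risk (default 5.0%/day) and mean duration (default
6.68 days) enter the cost pipeline nowhere; they exist for a consistency
check — the implied overall risk `r/(r + 1/d) = 25.03%` should be close to
the stated 26% (a warning is emitted beyond 10% relative discrepancy) — and
for the microsimulator.

## Uncertainty

Five inputs carry sampling uncertainty, with defaults (SE in parentheses):
`R = 0.26 (0.0153)`, `q_S = 0.24 (0.0408)`, `q_B = 0.036 (0.001)`,
`c_S = $911 ($911)`, `c_B = $3824 ($3824)`. They are treated as mutually
independent — the SEs come from separate literature sources with no
covariance information. For any estimator `T(θ)` the first-order
delta-method variance is `Σ_i (∂T/∂θ_i)² SE_i²`, with partials from central
finite differences (relative step 1e-6, absolute floor 1e-9; the cost map
is multilinear, so the numeric gradient is exact to rounding). For savings
the objective is the full pre-minus-post map, so the shared dependence of
both terms on `R` propagates through a single partial and is not
double-counted.

Confidence intervals are formed on the log scale,
`point · exp(±z · SE/point)` with `z` the exact normal quantile (1.959964
at 95%), giving multiplicatively symmetric intervals that respect the
positivity of costs. At the default inputs the relative SE of the cost
estimates is ≈ 0.73, dominated by the cost parameters' CV of 1; the log
interval spans roughly a factor of 4.15 either side of the point estimate.
A non-positive point estimate (zero savings under the zero intervention)
has no meaningful log interval and is reported degenerate with a warning.

The Monte-Carlo propagation routine is a numerical cross-check, not the
estimator: parameters are drawn independently from distributions that
respect their domains even at CV = 1 — gamma for costs (mean and SE
matched) and logit-normal for proportions (moment matched by least squares
over Gauss–Hermite quadrature). Draws violating `q_B <= q_S` are clipped to
the boundary and their fraction reported. In the small-CV regime the
empirical SD matches the delta SE within 5% (asserted at all SEs scaled by
0.05, 10^5 draws); at the default CV ≈ 1 cost inputs the two are *not*
expected to agree closely — the delta method is a first-order
approximation and the empirical distribution is strongly right-skewed.
This divergence is documented, not asserted.

## The microsimulator

`microsim.simulate_cohort` generates synthetic patient cohorts whose
structure matches the closed-form model exactly, serving as the brute-force
oracle: Bernoulli catheter placement at `p(1−f_p)`; exponential duration
with mean `d(1−f_d)`; bacteriuria when an exponential time with hazard
`λ_b = R/(d(1−R))` precedes removal; Bernoulli SUTI at `q_S` among
bacteriuric patients; Bernoulli BSI at `q_B/q_S` among SUTI patients (so
the marginal BSI risk given bacteriuria is `q_B`). The hazard is
back-derived from `R` and `d` rather than taken from the rounded 5%/day
figure, so the simulated bacteriuria fraction targets `R` exactly. The
nested SUTI→BSI construction is one consistent mechanism compatible with
the ordering assumption; the data identify only the two marginals, not the
joint. The BSI-without-SUTI trajectory is never generated.

What the simulator does **not** emulate about real data: hospital-level
heterogeneity in infection risk and quality of care, time-varying hazards,
recatheterization, length-of-stay correlation, and patient-level cost
variation (costs are point masses at 0, `c_S`, `c_B`). Agreement between
the simulator and the closed forms therefore validates internal
consistency of the implementation, not external validity of the model.

## Numerical and design choices

- Proportions live on the [0,1] scale internally; percentage inputs are
  converted once at the boundary.
- `q_B > q_S` is rejected at validation (the SUTI-only count would go
  negative), not clamped.
- The degenerate `R = 1` input bypasses the odds formula (only `f_d = 1`
  eliminates a sure event); `R` is otherwise required to be below 1 where
  the formula is applied.
- A log-interval half-width beyond the `exp` overflow threshold (~700)
  reports an infinite upper bound rather than raising.
- The default intervention grid covers 0–50% in 10% steps on both axes,
  which spans every scenario with published figures; grids must be sorted
  ascending within [0,1].
- Simulation sizes used by the test and acceptance suites: 2×10^5 patients
  for the cohort-vs-closed-form check (4 Monte-Carlo SEs), 10^6 draws for
  the competing-exponential check of the duration formula (3 binomial SEs),
  10^5 draws for the small-CV delta/MC agreement check. These give
  comfortable statistical resolution at second-scale runtimes.

## Known limitations

- Reproduction of the published dollar figures is bounded by input
  rounding: the inflation-adjusted costs are published rounded to $911 and
  $3824, leaving a ≤0.1% residual on point estimates (e.g. $37,850
  computed vs $37,868 published) and ≤0.7% on CI bounds; hence the 1%
  relative tolerance used in the acceptance checks.
- No intervention or opportunity costs, no inflation machinery, no
  hospital-quality variation, no covariances between inputs, no
  second-order delta correction, no Bayesian intervals.
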