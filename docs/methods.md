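# Methods

## Model structure

The unit of analysis is a cohort of sarcopenic patients entering at age
60.  A decision tree first splits each active strategy's cohort by
treatment acceptance and adherence (0.9 for every intervention, a stated
assumption of the reference analysis): acceptors enter an *on-treatment*
Markov arm, decliners an *off-treatment* arm identical to the
no-intervention natural history.  The no-intervention strategy runs the
off-treatment arm only.

Each arm is an annual-cycle Markov model over four states:

| state | meaning | cost / yr | utility / yr |
|---|---|---|---|
| `SARCOPENIC` | alive, no prior fracture | intervention + visits (on-treatment only) | 0.785 |
| `FRACTURE_YEAR` | first year after a fall-related fracture (one-cycle tunnel) | 12,588.214 | 0.785 − 0.25 |
| `POST_FRACTURE` | subsequent post-fracture years | 2,517.64 | 0.785 − 0.17 |
| `DEAD` | absorbing | 0 | 0 |

Within a cycle, death resolves first; survivors then fall with annual
probability `p_fall = 0.155` (reduced by treatment in the on-treatment
arm) and a fall leads to fracture with probability 0.33.  Fracture
survivors pass through the one-cycle tunnel into `POST_FRACTURE`, from
which re-fracture at the same (treatment-adjusted) fall/fracture
probabilities is allowed.  Mortality multipliers act on the hazard scale,
`q' = 1 − (1−q)^m`, which preserves probabilities at any age: hazard
ratio 1.6 for sarcopenia everywhere, additionally ×6.57 inside the
fracture-year tunnel (multipliers multiply, i.e. hazards add).  The
horizon is lifetime: cycles run to the end of the life table (age 110,
forced death), and rewards accrue to the state occupied at the start of
each cycle, discounted by `(1+r)^{−t}` with the first cycle undiscounted
and no half-cycle correction — the simplest fully reproducible
convention, stated here because the reference analysis does not specify
one.

Two structural conventions were fixed by matching the reference
analysis's published lifetime outcomes, since its text does not state
them:

* **Effect composition.**  Intervention effectiveness is reported as
  percent fall-risk reductions via three equally weighted indicators
  (muscle mass, strength, performance).  Each reported indicator
  contributes its full reduction and the contributions add (capped at
  100%): a strategy reporting only one indicator reduces fall risk by
  exactly that percentage.  Averaging over all three indicators with
  absent ones as zero — the main alternative reading — understates every
  published lifetime QALY gain by a factor of about three and was
  rejected; a multiplicative composition `1 − Π(1 − frr_i)` fits the
  single-indicator strategies equally well but understates the combined
  strategies' published increments (the decisive P+D-vs-D ICER lands 21%
  high instead of 10% low).
* **Cost attachment.**  Intervention and monitoring (visit + laboratory)
  costs accrue in the on-treatment `SARCOPENIC` state only; the published
  incremental costs imply 8.3–9.6 discounted treated-years per strategy,
  increasing with effectiveness — the discounted occupancy of the
  pre-fracture state, not of all alive states (~11.3).  The arm's
  fall-risk reduction nevertheless persists in all at-risk states.

Falls without fracture carry no cost or disutility; comorbidities,
indirect costs, and treatment switching are out of scope.

## Parameters and distributions

All parameters live in a YAML configuration (packaged reference:
`sarcocea/data/table2.yaml`).  Uncertain parameters carry a distribution
family fitted by closed-form moment matching:

* Beta (probabilities, utilities, discount rates, percent fall-risk
  reductions rescaled to [0, 100]): `α = m((m(1−m)/s²) − 1)`,
  `β = α(1−m)/m` on the rescaled support.
* Gamma (costs): `shape = (m/s)²`, `scale = s²/m`.
* Log-normal (mortality HR 1.6 (1.24–2.06), fracture-year RR 6.57
  (5.54–7.29)): `μ = ln(point)`, `σ = (ln hi − ln lo)/(2·1.96)`.  The
  median and the 95%-quantile ratio are reproduced exactly; the endpoints
  themselves only up to the reported CIs' slight log-asymmetry (≤4%).

Reported 95% CIs are converted to sds via half-width/1.96 where a
moment fit needs one; discount-rate ranges (costs 0.02–0.10, outcomes
0.03–0.08) become Beta distributions rescaled to the range with mean at
the base value and `sd = width/(2·1.96)`.  The vitamin-D-alone annual
cost is not reported directly and is recovered as the (P+D) − P cost
difference, $129.276/yr (the (D+E) − E difference agrees to three
decimals); its sd uses the 20%-of-mean convention the reference analysis
applies when no uncertainty is reported.  Visit/laboratory cost
($400.409/yr) and the age-60 background death probability carry no
uncertainty and stay fixed in PSA.  Per-strategy effects are sampled
independently (no correlation structure is reported).  The
willingness-to-pay threshold ($25,249.13/QALY) and the PPP conversion
factor (29,704 Rial/$) are decision-rule constants, never sampled.

## Background mortality

No national life table is distributed with the reference analysis, so the
package synthesises one from a Gompertz hazard anchored at the single
published point: annual death probability 0.0095 at age 60.  With
`h(a) = −ln(1−0.0095)·e^{slope·(a−60)}` and `qx = 1 − e^{−h}`, the
default slope 0.085/yr corresponds to the canonical adult-mortality
doubling time of ~8 years and puts the discounted sarcopenic survival
annuity at 10.5 years — inside the 10–12 band implied by the reference
lifetime QALYs (8.1–8.7 at utility 0.785).  Death is forced at age 110.
Users can substitute a real table via `read_life_table` (CSV `age,qx`) or
the `--lifetable` CLI flag.

## Analyses

* **Frontier / decision.**  Strategies sorted by cost; strictly dominated
  ones removed (another strategy no costlier and at least as effective),
  then extendedly dominated ones (ICER exceeding the next frontier
  step's) until frontier ICERs strictly increase.  Ties break toward
  lower cost, then name.  The decision at threshold λ is the highest-QALY
  frontier strategy with step ICER ≤ λ, equivalently the NMB maximiser.
* **Tornado.**  Each uncertain parameter swept across its reported
  95% interval (or fitted 2.5/97.5 quantiles) with all others at base;
  outcome is the incremental NMB of the two top frontier strategies by
  default, or any strategy's absolute NMB.  On absolute NMB the mortality
  hazard ratio and the sarcopenic utility dominate among the
  epidemiological parameters, as in the reference analysis.
* **PSA.**  1000 joint draws by default; one draw is shared by all
  strategies within an iteration (common random numbers).  Acceptability
  at λ is the fraction of draws in which a strategy attains the maximal
  NMB (exact ties split equally); the CEAC evaluates this on a grid
  (default 0 to 3λ in 60 steps).
* **EVPI.**  Per person, `E[maxₛ NMBₛ] − maxₛ E[NMBₛ]`, with the average
  cost/effectiveness increments under perfect information taken between
  the per-draw winner and the strategy maximising expected NMB.  No
  population scaling and no partial (EVPPI) decomposition.

## Synthetic data and what the tests show

The synthetic-data module generates every input the pipeline needs: the
packaged reference configuration (checksum-locked in tests), Gompertz life
tables, closed-form toy scenarios (annuity and truncated-geometric
expectations computed independently of the engine), random valid
configurations, and an individual-level microsimulation that re-implements
the transition rows by sampling trajectories.  Tests verify the cohort
engine against the closed forms (1e-10), the microsimulation (within 3
Monte-Carlo standard errors on the base case and random scenarios, 30–60k
paths), and a brute-force dominance oracle for the frontier (100 random
instances).  These checks validate the arithmetic of the implementation;
they cannot validate the epidemiological assumptions themselves (fall and
fracture rates constant in age, a single tunnel year, no comorbidities)
against real cohorts.

## Problem sizes

The default test suite and the acceptance script use the full model
(51-year horizon, 8 strategies) everywhere; the PSA runs its full 1000
iterations (~15 s) and microsimulation oracles use 30–60k paths —
sampling error small enough that a 3-standard-error band detects relative
engine errors of ~0.5%.

## Known limitations

* The reference analysis's national life table is unpublished; the
  Gompertz stand-in reproduces lifetime QALYs within ~2% and costs within
  ~8%, but quantities formed from small differences inherit larger
  relative errors.  Across slopes 0.06–0.12/yr the P+D-vs-D ICER moves
  over roughly $110k–131k/QALY (vitamin D alone remains the decision
  throughout); the suite pins this trace.
* Value-of-information quantities are the most fragile outputs: with
  every distribution sampled, the no-intervention strategy attains
  maximal NMB in ~8–10% of draws (low draws of utility, fall and fracture
  probabilities, and the vitamin-D effect), which lifts per-person EVPI
  to ~$470–710 across seeds, against the reference estimate of $273.62
  computed from a PSA whose exact sampled subset is unreported ("some
  uncertain variables").  Restricting sampling to strategy-level
  parameters roughly halves the EVPI and brings the winner distribution
  close to the reference figures; the package deliberately samples
  everything with a reported distribution and documents the gap rather
  than fitting the sampled subset to the published outputs.
* Utility decrements are additive and state utilities are floored at
  zero in extreme draws; fall risk is age-constant; adherence is a single
  lifetime split, not a per-cycle process.
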