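# Methods

This note documents the models implemented in `mgdb`, their
assumptions, the constants that drive them, and the choices made where
the design was genuinely open.

## Access to optimal care

Access is the fraction of a population able to reach the standard of
congenital-disorder care of an equitable high-income setting. It is
proxied from the infant mortality rate because IMR is strongly
correlated with the alternatives (neonatal mortality, life expectancy,
urbanisation) and has the longest available country series.

The stepped reference mapping (`DEFAULT_STEPPED_TABLE`) assigns access
1.0, 0.5, 0.15, 0.05, 0.0 to the IMR bands [0,10), [10,25), [25,55),
[55,100), [100,∞). The printed band edges are integers (≤9, 10–24, …);
half-open real intervals extend them to real-valued IMRs without gaps.

The smooth curve is the complement of a regularized incomplete beta
CDF rescaled to [9, 100], clamped to 1 below 9 and 0 above 100. Its
two shape parameters are fitted by least squares to the interior band
midpoints (17, 0.50), (39.5, 0.15), (77, 0.05); the calibration is
accepted only if every anchor is matched within ±0.05 (achieved: max
deviation 0.039 at the (77, 0.05) anchor). The beta family was chosen
because a two-parameter CDF on a bounded support is the simplest
family that is monotone, clamps exactly at both ends, and is flexible
enough to match three interior anchors; no separate smoothing step is
applied. Alternative parameterizations that fit the anchors within the
same tolerance would be interchangeable — the anchor tolerance, not
the coefficients, is the contract.

### Consanguinity adjustment

Consanguinity-associated infant deaths inflate IMR without indicating
worse services. They are estimated as

```
cIMR = (α / 0.0625) · e_nocare · (1 − ρ · access)
```

where α is the population mean coefficient of consanguinity, 0.0625
the first-cousin-offspring reference, `e_nocare` the excess infant
deaths per 1000 at that reference with no care (default 30, order of
magnitude from the consanguinity excess-mortality literature), and ρ
the fraction of those deaths avertable with optimal care (default
0.8). Both are configurable (`consanguinity.e_nocare`,
`consanguinity.rho`).

Because cIMR depends on access and access on the adjusted IMR, the
subtraction is iterated: each round recomputes cIMR at the latest
access estimate and re-subtracts from the *original* IMR. The first
round over-reduces (it uses the too-low unadjusted access); the second
corrects most of the over-reduction, and further rounds change little,
so exactly two rounds are run by default (`consanguinity.n_iter`). A
convergence test verifies that the n→∞ limit of this trace equals a
brute-force fixed-point solve at tolerance 1e−9.

Adjusted IMRs are clamped at `imr_floor` (default 1.0 per 1000) so the
curve argument stays positive; clamping is recorded on the estimate
and logged. HIV-attributable infant mortality is then subtracted the
same way. Both adjustments only lower the IMR, so adjusted access is
never below unadjusted access; the adjustment's effect on access peaks
for IMR in the 10–35 band (the steep part of the development curve),
which the test suite asserts on a sweep at α = 0.03.

## Folic-acid fortification

Constants (`folate.*`): residual spina bifida + anencephaly rate after
full fortification 0.7/1000; encephalocoele share of neural tube
defects 11.5%; total non-folate-preventable floor 0.77/1000. The floor
is an independent constant, not recomputed from the first two (their
arithmetic composition gives 0.78–0.79, so the printed 0.77 is taken
as authoritative).

Dose response: the fraction of preventable cases remaining at full
reach is `RR(d) = exp(−k_dose·d)` with `k_dose = 1.65` per ppm
(ppm = mg folic acid per kg flour), the smallest round value for which
a 2 ppm dose brings the post-fortification total below 1/1000 for any
baseline up to 6.5/1000 — the published calibration anchor. A
tabulated dose–response (`folate.dose_response_table`, piecewise
linear) can replace the exponential. Post-fortification prevalence is

```
post = baseline − reach · (baseline − 0.77) · (1 − RR(d))
```

bounded by the floor and the baseline. Voluntary fortification and
supplementation are assumed to have no effect; observed pre/post
prevalences, when supplied, bypass the model. Fortification acts
equally on all NTD subtypes, so subtype splits keep baseline shares.
Collateral proportional reductions of orofacial clefts and congenital
heart disease default to a maximal 5% (`folate.ofc_max_effect`,
`folate.chd_max_effect`) scaled by reach and dose response — the
effect is described qualitatively as small in the literature, so 5% is
a placeholder, clearly configurable. Vitamin B12 effects are not
modelled.

## Genetic risk information for recessive disorders

Baseline affected birth prevalence uses consanguinity-augmented
Hardy–Weinberg: `q² + α·q·(1−q)`. At-risk couples (both carriers) have
affected births with probability 1/4.

Let N be the family-size norm (birth slots per couple, evaluated at
real N; the country's total fertility rate in the pipeline).

* **Retrospective** information arrives at the first affected birth.
  Maximal-effect rule: counselled couples stop there. Expected
  affected births fall from N/4 to `1 − 0.75^N`, a proportional fall
  `1 − (1 − 0.75^N)/(N/4)` — 0.452 at N=6 (the "~50% at six or more"
  anchor) and 0.179 at the global norm N=2.5 (the "~15%" anchor).
  With prenatal diagnosis the couple continues to N, and each affected
  pregnancy after the first affected birth is terminated with
  probability u, giving fall `u · (N/4 − (1−0.75^N))/(N/4)`.
* **Prospective** identification (carrier screening before any
  affected birth): couples stop at two healthy children, so expected
  affected births are the negative-binomial mean 2/3, a fall
  `1 − (2/3)/(N/4)`, clamped to 0 for N < 8/3 (no effect below a
  family norm of about 3). With prenatal diagnosis every affected
  pregnancy is diagnosable and the fall equals the uptake u (0.97
  reproduces the >95% reductions reported for β-thalassaemia
  screening).

Note one consequence of these two stopping rules: below N ≈ 3.8 the
retrospective fall *exceeds* the prospective fall, because stopping at
the first affected birth is the more drastic behaviour for small
families; the intuitive ordering (earlier detection does at least as
well) holds from N ≈ 3.8 upward, and the tests assert it only for
N ≥ 4.

Counselling-adjusted prevalence composes the two channels:
`baseline · [p(1 − F_pro) + (1 − p)(1 − r·F_retro)]` with prospective
coverage p (default 0 without a screening programme) and retrospective
coverage r (default: the estimated access, since diagnosis of the
first affected child requires services). Replacement of affected
children who died is noted but not modelled. A seeded Monte-Carlo
simulation of 100 000 couples per scenario (an independent per-couple
implementation of each stopping rule) agrees with the closed forms
within three standard errors across N ∈ {2,3,4,6,8} and PND uptakes
{none, 0.15, 0.5, 0.97}.

## Anti-D and termination of pregnancy

Anti-D coverage is at least the estimated access; where anti-D is
standard obstetric practice, coverage is `max(access, ANC4)` (ANC4 =
four-antenatal-visit coverage), efficacy 1.0 by default
(`antid.efficacy`). Prevented cases are `baseline × coverage ×
efficacy`.

Termination of pregnancy for fetal impairment uses four country
groups: A (legal, registry data — observed rates pass through, capped
at the affected prevalence, with a logged warning when the cap binds),
B (legal, no data — prenatal-diagnosis access equals the optimal-care
estimate and uptake equals the EUROCAT average), C (status unclear but
widespread availability documented — treated as B; group membership is
a country-table column, not a hardcoded list), D (illegal — zero).
Down syndrome and spina bifida uptakes are multiplied by 0.5
(`top.restricted_multiplier`) unless the country has an explicit
universal screening policy. EUROCAT average uptakes are input data;
the shipped values are synthetic placeholders of plausible magnitude.
Groups C and D likely undercount terminations; no correction is
attempted.

## Outcome envelope

All rates are per 1000 *total* births (terminations inside the
denominator), declared in the output headers; this convention keeps
the envelope closed under aggregation. Two conservation identities are
enforced to 1e−9 on every envelope:

```
terminations + stillbirths + livebirths = post-prevention prevalence
under-5 deaths + cured + mild-moderate + severe = livebirths
```

Access is binary at the individual level: a fraction `access` of
affected livebirths experiences the with-care under-5 mortality and
the with-care survivor disability shares, the remainder the no-care
ones. Survivor disability shares are therefore mixed with
survivor-mass weights per stratum, not the raw access fraction — e.g.
with L = 1, access = 0.5, mortality 0.1 (care) / 0.8 (no care), the
care stratum contributes 0.45 survivors and the no-care stratum 0.10,
so the care disability profile gets weight 0.45/0.55, not 0.5. Mean
age at death is the share-weighted mean of configurable under-5
death-age-band midpoints, reported as missing when there are no
deaths; full life-table years-of-life-lost integration is deliberately
out of scope.

In the pipeline, counselling for recessive disorders is applied
*without* its prenatal-diagnosis variant, and prenatal-diagnosis
terminations are then modelled once by the TOP stage — this keeps each
averted birth counted exactly once in the envelope.

Aggregation to regions (and the world) uses livebirths-weighted means
for every rate and access fraction, and sums for counts; it is
invariant to country order and to splitting a country into equal-rate
halves.

## Synthetic data

`mgdb.fixtures.generate_fixtures(n, seed)` emulates the *joint
structure* of the indicator data the model consumes: IMR log-uniform
on [2, 120] (covering all five access bands and the steep 10–35
window), consanguinity zero for half the countries and uniform
[0.005, 0.04] for the rest, fertility rising and antenatal coverage
falling with IMR, HIV-attributable infant mortality in a flagged
quarter of high-IMR countries, TOP groups sampled over A–D, and four
condition profiles, one per modelled pathway. It is deterministic
given the seed. It does **not** emulate real-world features such as
correlated region blocks, time trends, measurement error in IMR, or
realistic observed TOP registries (group-A observed rates are a single
country-level per-1000 value applied to each condition). Passing tests
on these fixtures therefore demonstrates internal consistency,
conservation and calibrated behaviour of the models — not agreement
with any real country's data, which would require the external
indicator sources.

## Numerical choices

* Curve fitting: `scipy.optimize.least_squares` on log-shape
  parameters, initialised at (1, 1); failure to meet the ±0.05 anchor
  tolerance raises a calibration error (CLI exit code 3).
* All rate floors/clamps (`imr_floor` 1.0/1000, folate floor, TOP cap
  at prevalence) are logged when they bind, never silent.
* Pipeline problem size: the shipped synthetic world is 50 countries ×
  4 conditions (200 envelopes, ~1 s end to end); the Monte-Carlo
  couple simulations use 100 000 couples per scenario.
* Degenerate inputs: zero affected prevalence yields an all-zero
  envelope with missing mean age at death; zero aggregation weight is
  an error.
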