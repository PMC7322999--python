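# Methods

## Model

The package estimates capability value sets by treating reported subjective
well-being (SWB) as a proxy for experienced utility. For respondent *i* with
capability levels `L_id ∈ {1,2,3,4}` on the five dimensions *d* of an ICECAP
instrument,

    SWB_i = β0 + Σ_d Σ_{l=2..4} 1[L_id = l] · β_dl + SES_i'γ + ε_i

with level 1 (full capability) as the reference category, so each `β_dl` is
the *disutility* of being at level *l* of dimension *d*. The response is the
unweighted average of two unit-rescaled SWB measures — Cantril's ladder
(CL/10) and the Satisfaction with Life Scale total ((SWLS−5)/30) — which
damps measure-specific response error; CL-only and SWLS-only responses are
available as sensitivity modes.

Assumptions worth making explicit: SWB is treated as cardinal and
interpersonally comparable; capability levels are exogenous to SWB (no
reverse causation or omitted common causes); SES enters additively; and the
error is homoskedastic normal (for the Tobit exactly, for OLS only via the
classical SE formula).

### Estimators

* **OLS** with classical standard errors, on the *reduced* (levels only) and
  *full* (levels + SES) designs.
* **Restricted least squares** for monotonicity repairs. A monotonicity
  violation is either a positive level coefficient or a worse level with
  strictly smaller disutility magnitude than a better one. The default
  repair policy mirrors practice: only positive coefficients are fixed to
  zero (policy `"zero"`); policy `"tie"` additionally pins a non-monotone
  level to its better neighbour's estimate. Restricted LS is computed via a
  Gaussian GLM with linear equality constraints, which reproduces the
  column-deletion solution (coefficients and SEs) exactly for zero
  constraints; constrained entries are reported with SE 0.
* **Two-sided Tobit** at bounds [0, 1] for the censored nature of the SWB
  index: uncensored rows contribute the normal density of the residual,
  rows at a bound the tail probability of the latent variable. The MLE is
  maximised by BFGS with an analytic score and `log σ` parameterisation,
  with a Nelder–Mead fallback; SEs come from the observed information. With
  no observation at a bound the estimates coincide with OLS (verified to
  ~1e-7), with `σ̂` differing by the MLE-vs-degrees-of-freedom convention
  `√((n−p)/n)`.

### From coefficients to a value set

`rescale_disutilities` multiplies all 15 level coefficients by
`1/|Σ_d β_d4|`, anchoring the worst describable state (44444) one full unit
below the best (11111). `reverse_code` then switches the reference to the
worst level: `u(d,l) = |δ(d,4)| − |δ(d,l)|`, so every dimension's level 4
carries 0 and the level-1 increments sum to 1. Profile scores are sums of
the selected increments. The value set is *not* anchored to the state
"dead"; 0 means "no capabilities", not death, matching how the published
decision-utility weights are scaled.

Bootstrap uncertainty: respondents are resampled with replacement B times
(default 500), the regression — with any constraints re-imposed — and the
rescaling are repeated, and the SE of each entry is the SD (ddof=1) of its
replicate values. Percentile intervals are available. Rank-deficient
replicates are redrawn; more than 10% redraws raises an error. Comparisons
with the decision-utility weights use t = (EU − DU)/SE_boot against a
standard normal, treating DU as a fixed constant: its sampling uncertainty
was never published, so the tests understate total uncertainty — a caveat,
not something the package can repair.

### Which model feeds the tariff

For ICECAP-O the published experienced-utility tariff tracks the
*constrained* full model (role level 2 fixed to zero); for ICECAP-A the
*full* model (no constraint was needed). The package defaults follow that
choice but both sources are selectable.

## Synthetic data generator

The generator emulates the structure the regression assumes, not any real
population:

* **Capability levels**: a single-factor Gaussian copula. With latent
  `z_id = √ρ·c_i + √(1−ρ)·e_id`, every pair of dimensions has latent
  correlation ρ (`dependence`, default 0.3 — the one published cross-
  dimension correlation anecdote is r = 0.25). Per-dimension cut-points are
  the normal quantiles of the cumulative level marginals, so marginals are
  matched exactly in expectation. Default marginals put 1.6–8% of mass on
  the worst level, the range reported across dimensions in the two surveys.
* **SES**: drawn independently of capability levels (they enter the model
  only as additive controls); marginals follow the published sample
  summaries (male share, age mean/SD within the instrument's age range,
  education, marriage, financial-difficulty shares, log-normal
  wealth/income around the published medians).
* **SWB**: latent SWB is the linear model at the drawn levels and SES plus
  `Normal(0, noise_sd)` (default 0.07), optionally clamped to [0, 1]
  (`censor`, default on). CL and SWLS are produced from that one latent
  value by adding independent `Normal(0, measurement_sd)` draws, mapping to
  the native integer scales, rounding, and clipping to the scale bounds
  (clipping, not redrawing). The composite is therefore a noise-reduced
  proxy of latent SWB.

**Generating coefficients.** The default truth is the published full-model
column with two repairs forced by table rounding: the printed age
coefficients (0.010 and −0.000) are unusable at face value (they add ~0.75
to SWB at the mean age), so both are set to zero and the intercept is
calibrated so that expected SWB at full capability with average SES equals
the published reduced-model intercept (0.868 / 0.817). `measurement_sd`
defaults to 0.10, which reproduces the published R² scale (≈0.63–0.66) of
the full-model fit under `noise_sd = 0.07`.

**What passing tests do and do not show.** The generator matches marginal
level frequencies, a single pairwise dependence parameter, independent SES,
and a correctly specified linear SWB model. Real survey data have none of
these guarantees — capability–SES dependence, item-level response styles,
nonresponse, and misspecification are all absent — so recovery results on
synthetic data certify the *pipeline*, not the substantive estimates.
A known property of the measurement model: because CL and SWLS are clipped
at their scale maxima, larger measurement noise attenuates the level
contrasts slightly (up to about one SE at n = 5000 with
`measurement_sd = 0.10`); the parameter-recovery test therefore runs under
the structural error alone (`measurement_sd = 0`).

## Numerical choices

* Rescaling of the raw SWB measures uses the instruments' theoretical
  ranges (0–10, 5–35); the alternative (observed ranges) is not implemented
  as a default but trivially reachable by pre-transforming the input.
* Classical homoskedastic OLS SEs (no robust/clustered options).
* Complete-case analysis: rows with any missing field are dropped with a
  logged count.
* The optional worst-level-anywhere dummy is off by default.
* Wealth enters in £ millions, monthly income in £; age and age² in years,
  unscaled.
* Bootstrap SE = SD of replicates, not percentile half-width (percentile
  intervals available); constraints are re-imposed in every replicate, with
  a per-replicate re-detection variant available via the violation-derived
  constraint helper.
* Tariffs are rounded to 3 decimals only in display tables; all internal
  arithmetic is full precision. Degenerate inputs raise: a zero level-4
  coefficient sum (undefined scale), a fully censored response (Tobit), an
  empty respondent table.
* Determinism: all randomness flows from `numpy.random.default_rng(seed)`;
  a fixed config (including seed) yields byte-identical generated tables
  and pipeline outputs, and the run manifest records config, seed and
  library versions.

## Test problem sizes

Unit and acceptance tests run on synthetic samples of 516–5,000 respondents
(50 seeds for the recovery check, B = 2,000 for the bootstrap-calibration
check, 100,000 draws for marginal-fidelity checks), sizes at which the
checked properties are statistically decisive while the whole suite stays
fast.

## Known limitations

* Endogeneity of capability levels and omitted SWB determinants
  (personality, social environment) are untreated — estimates are
  associations.
* The t-tests against decision-utility weights ignore DU sampling error.
* The synthetic generator cannot validate behaviour under informative
  missingness or measure-specific differential item functioning.
* Printed coefficients carry 3-decimal rounding; reproduction tolerances
  (±0.002 on tariff entries, ±0.005 on profile scores) reflect that, not
  estimation error.
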