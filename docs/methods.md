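# Methods

## The decision model

Four strategies for fluid resuscitation in severe childhood malaria are
compared by incremental net monetary benefit relative to no fluid:

    B_j(θ) = (expit(α) − expit(α + dM_j)) · (W·qM − CH − pL·h2(pB, dS)·(W·qS + CS)) − CF_j

where `h2(pB, dS) = pB·e^{dS}/(1 + pB·e^{dS}) = expit(dS + ln pB)` is the
probability of neurological sequelae (NS) among patients who survive *only
because* of treatment.  The model assumes: mortality effects are additive on
the log-odds scale; patients who would have survived anyway keep the
baseline NS risk `pB`, while "saved" patients have their NS odds shifted by
`dS` applied to `ln pB` (as the model is written, the shift composes with
`ln pB`, not `logit pB` — both limits are implemented as stated and a
boundary evaluation at `pB ∈ {0,1}` is logged); short-term NS persists long
term with probability `pL`; long-term NS costs `CS` and removes `qS` QALYs.

An equivalent four-outcome enumeration (death / NS-free survival /
short-term NS / long-term NS) is implemented independently
(`outcome_accounting_net_benefit`) and required to agree with the closed
form to 10⁻⁹ dollars; this algebraic identity is the model's primary
self-check.  One caveat the enumeration makes visible: on draws where a
fluid *increases* mortality (which the model permits), the "saved" mass
`expit(α) − expit(α+dM_j)` is negative and the with-fluid outcome split is
an accounting identity rather than a probability distribution — individual
entries can leave [0, 1] while still summing to one and reproducing the
closed form exactly.  No clipping is applied; the closed form is the
authority.

### Economic constants and treatment pairing

`CH = $60` (five hospital days at $12), `CS = $20,000`, fluid costs $35
(albumin), $1 (saline), $12.50 (gelofusine), reference cost 0, `W` in
USD/QALY (default grid 0–4000).  The three mortality log-odds-ratio symbols
carry the published posterior moments: `d2M` (mean −0.31, var 0.51), `d3M`
(−2.34, 0.64), `d4M` (−0.19, 1.81).  The published tables are internally
contradictory about which fluid each symbol names; the pairing used here —
`d2M`↔saline, `d3M`↔albumin, `d4M`↔gelofusine — is the only one consistent
with the published results narrative (albumin as the sole effect whose
credible interval excludes zero, and the albumin/gelofusine switching
threshold near $269/QALY).  The pairing is data, not code: pass a different
`DecisionContext.treatments` tuple to change it.

## Posterior reconstruction

The original analysis represented uncertainty with 5 million MCMC draws
from a Bayesian evidence synthesis of three pilot studies.  Those draws and
the underlying pilot data are unavailable, so `posterior.py` rebuilds a
joint distribution from published summaries:

| parameter | family | values |
|---|---|---|
| α | Normal | mean −1.07, var 0.11 |
| d2M, d3M, d4M, dS | multivariate Normal | means (−0.31, −2.34, −0.19, 1.88); vars (0.51, 0.64, 1.81, 4.52); correlations d2–d3 0.64, d2–d4 0.44, d3–d4 0.51, dS–(d2,d3,d4) (0.25, 0.27, 0.27) |
| pB | Beta(1, 9) | mean 0.10 |
| pL | Beta(1, 1) | uniform |
| qM | Normal | mean 19.99, var 24.97 |
| qS | Normal(5, 3.16²) truncated at 0 | implied mean 5.38, var 7.93 |

Dependence is a Gaussian copula: latent standard normals with the published
correlation matrix (nearest-PSD-repaired by eigenvalue clipping at
tolerance 10⁻⁸ if needed), pushed through each marginal quantile function.
For the jointly-estimated normal block this coincides with direct
multivariate-normal sampling.  Two published values are knowingly
overridden: the summary table's `pB` "variance" of 0.04 is impossible for
the stated Beta(1, 9) family (whose variance is ≈0.0082) and the Beta form
wins; the quoted 95% interval for `pB` (0.6%–28.5%) is only roughly
consistent with Beta(1, 9) (exact quantiles 0.28%–33.6%).  `moment_report`
compares any sample against all specified moments with z-scores.

**What the reconstruction cannot preserve.**  It is moment-matched, not
shape-matched: any skewness of the true posterior — most plausible for `dS`
(variance 4.52 from very few NS events) and `d4M` — is lost.  This matters
because `h2` saturates through an inverse logit, so the tails of `dS` drive
the cost side of the decision at low willingness to pay.  Consequences
observed at N = 10⁶, W = $250: EVPI and the large multi-parameter EVPPIs
land within a few percent of the published values, but the reconstruction
is systematically *more* decision-uncertain near $250 than the original
posterior — the switching threshold comes out near $240 (published $269),
the albumin CEAC near 62% (published 54%), and the single-parameter EVPPIs
for `qM`, `pB`, `dS` run 20–50% high.  All estimators cross-validate
against nested Monte Carlo and quadrature oracles *on the reconstructed
posterior*, so these gaps measure posterior-shape error, not estimator
error.  Passing tests therefore demonstrate correctness of the methods, and
only approximate reproduction of the original numbers.

## Estimators

`j*` is fixed once per analysis as the treatment with maximal full-sample
mean net benefit; argmax ties break to the lowest treatment index
(measure-zero under continuous draws).  Every estimator reports a Monte
Carlo standard error computed from the per-draw regret terms; the O(1/N)
bias induced by the outer max is documented here and not corrected.

**Mean plug-in (m1/m2).**  Valid only when the complement is a subset of
{qM, qS, pL} (elsewhere the net benefit is nonlinear through the inverse
logit or the `h2` term, or the complement is internally correlated).
Admissibility is enforced by an explicit registry for this model rather
than symbolic analysis; an inadmissible request raises, naming the
offending parameters, instead of returning a silently biased number.

**Reparameterized plug-in (m3).**  The net benefit is linear in
`β1_j = expit(α) − expit(α + dM_j)` and `β2_j = β1_j·h2`, both independent
of {qM, qS, pL}; their full-sample means are substituted.

**Quantile-averaged Taylor (m4).**  For focal {dM, dS} the conditional net
benefit factorizes into `E[expit(α + dM_j) | dM_j]` (expansion over α) and
`E[expit(dS + ln pB) | dS]` (expansion over ln pB).  Expansions are
second-order about each equal-probability segment mean (default 4 segments,
the "interquartile means"), weighted by segment mass; segment moments are
empirical, so the method works for any marginal.  Fourth-order expansions
are available (closed-form inverse-logit derivatives; the inverse-cloglog
is supplied to second order with `h'' = −H·ln H·(1 + ln H)`,
`H = exp(−exp(x))` — the second derivative was re-derived and verified by
finite differences and quadrature).  Approximated probabilities are clipped
to [0, 1] and clip counts reported in the estimate settings.  Rationale for
the default: a single expansion degrades with the nonfocal variance, and
averaging local second-order expansions over four segments beats a single
fourth-order expansion in max error (verified against Gauss–Hermite over
shift ∈ [−4, 4] at sd 1).  For focal {α, pB} the correlated (dM_j, dS)
block breaks full factorization of the cross term
`E[expit(α+dM_j)·h2 | α, pB]`; it is approximated by the product of the two
univariate segment expansions plus a first-order delta-method covariance
correction `expit'(α+μ_d)·expit'(ln pB+μ_s)·cov(dM_j, dS)`.

**Restricted cubic splines (m5).**  For a scalar focal parameter correlated
with the complement, the conditional means of the two nonlinear terms
(`g1_j = expit(α) − expit(α+dM_j)` and `g2_j = g1_j·h2`) are estimated by
sorting the joint draws on the focal value, averaging within `M_B = 100`
equal-count bins, and fitting an unweighted OLS natural cubic spline
(default 10 equally spaced knots) to the bin means per treatment.
Equal-count binning keeps bin-mean standard errors roughly homoscedastic,
which is why the regression is unweighted.  The basis is the
truncated-power natural-spline construction, so linear tails and C²
smoothness hold for every coefficient vector by construction.  Numerical
choices: knots span the first to last *internal* bin boundaries (≈1st–99th
percentiles) — anchoring a boundary knot at the sample extreme lets a
handful of tail draws set the extrapolation slope and destabilizes the
estimate; and for focal `pB` the spline axis is `ln pB`, the scale on which
`pB` enters the net benefit — an exact monotone reparameterization of the
conditioning variable that makes the conditional-mean curves
near-polynomial (estimates then agree to ≈0.3% between 5 and 15 knots,
versus ≈6% knot-sensitivity on the raw axis).  The reference treatment's
conditional net benefit is identically zero by construction, never fitted.
Multivariate focal sets are out of scope (they would need multivariate
regression splines).

**Nested Monte Carlo baseline.**  Outer draws are the leading rows of the
joint sample; inner draws resample complement rows from the joint sample
(marginal) or, with `conditional=True`, from the copula conditional law of
the complement given each outer focal value (latent-Gaussian conditioning,
vectorized).  Marginal inner resampling with a correlated focal set logs a
warning: it is downward-biased, demonstrated on the correlated toy model
where it underestimates the quadrature oracle by ~40%.  Finite inner
samples bias the estimator upward through the max over noisy inner means;
on this model with 1000 inner draws the bias for focal {qM} measures
≈ +1.3% (the original analysis reported ≈3% on its posterior — the
magnitude depends on posterior shape).  The bias is measured with a paired
design (nested and single-step regrets on shared outer draws), which
removes the shared outer variance and resolves the margin at ≈6 standard
errors with 2×10⁴ outer draws.

## Oracles

`gh_expectation` integrates smooth functions of a normal variable by
Gauss–Hermite rules with node doubling to 10⁻¹⁰.  `quadrature_evppi`
computes EVPPI on Gaussian toy models (dimension ≤ 3) by nested
deterministic quadrature: smooth inner conditional expectations by tensor
Gauss–Hermite; the outer expectation of the kinked max-regret by *adaptive*
Gaussian-weight quadrature (Gauss–Hermite alone oscillates at the percent
level on kinked integrands).  The oracle reproduces the closed-form normal
tail expectation of the linear toy to 10⁻⁶.  The four-model toy suite
(linear / product / independent-expit / correlated-expit) spans the
plug-in, Taylor and spline regimes and ships in the package so user models
can be validated the same way.

## Problem sizes

Sample sizes are chosen for a single CPU: the headline grid and
reproduction checks run once per session at N = 10⁶ (the original analysis
used 5×10⁶; estimates at 10⁶ carry mc standard errors under $2 on values of
hundreds of dollars); plug-in-vs-nested agreement at 4000 outer × 4000
inner; the inner-bias measurement at 2×10⁴ outer × 1000 inner (paired);
toy-model oracle recovery at 5×10⁴ draws.  All randomness is seeded;
seeded runs are bit-reproducible.

## Known limitations

* The reconstruction-vs-original gaps described above: single-parameter
  EVPPIs for qM, pB, dS, the $250 CEAC and the switching threshold
  reproduce only to within 20–50%, with a consistent sign (more residual
  decision uncertainty near $250 than the original posterior).
* Admissibility is a registry for this model, not symbolic analysis of an
  arbitrary net-benefit expression.
* No EVSI, no multivariate splines, no discounting machinery or severity
  strata; the CLI writes CSVs only (figures are regenerable from them).
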