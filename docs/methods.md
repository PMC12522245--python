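# Methods

## The estimation problem

Given a sample of "healthy" adults aged 45–85 with PASE totals `y`,
interview ages `x`, and survey weights `w`, the goal is the family of age
conditional quantile curves `Q_p(x)` for p in {5, 10, 20, 25, 50, 75, 80,
90, 95} per cent, separately by sex (and optionally by interview season).
Two estimation routes are implemented and compared; the deliverable is a
norm table (integer ages 45–85 by the nine percentiles) plus the inverse
lookup score -> percentile.

## Distribution families

The distributional route models `y | x ~ D(mu(x), sigma(x), nu(x),
tau(x))` for a four-parameter family `D`. Ten families are implemented in
`pasenorm.distributions`, under their canonical parameterizations from the
GAMLSS distributions literature; each class docstring states its defining
transform. Briefly:

* **SHASHo / SHASHo2** (sinh-arcsinh): `r = sinh(tau*asinh(z) - nu)` is
  standard normal, `z = (y-mu)/sigma` (SHASHo2 uses `sigma*tau` as scale).
  `nu` skews, `tau` tunes tail weight; `nu=0, tau=1` *is* the normal.
* **SHASH**: `r = [exp(tau*s) - exp(-nu*s)]/2`, `s = asinh(z)`; separate
  left (`nu>0`) and right (`tau>0`) tail control; normal at `nu=tau=1`.
* **JSU / JSUo** (Johnson's SU): `nu + tau*asinh(z)` standard normal
  (JSUo); JSU re-centres so `mu, sigma` are location/scale.
* **SEP1 / SEP2** (skew exponential power, Azzalini-type): symmetric power
  exponential base `f(z) ∝ exp(-|z|^tau)` times a skewing CDF factor.
* **SEP4** (two-piece): `f(z) ∝ exp(-|z|^nu)` left of the mode and
  `exp(-z^tau)` right of it; closed-form CDF via incomplete gamma.
* **ST1** (Azzalini skew-t), **ST5** (Jones–Faddy skew-t; closed-form CDF
  via the incomplete beta).

Densities are computed in log space. CDF/quantile use closed forms where
they exist; SEP1, SEP2 and ST1 fall back to adaptive quadrature
(`scipy.integrate.quad`) and bracketed root-finding (tolerance 1e-12 on
the root), with a dense cumulative-Simpson grid plus monotone PCHIP
interpolation for large vectorized CDF calls. Sampling is exact:
inverse-CDF where closed, and the sign-flip selection representation for
the Azzalini-type families (draw `Z` from the symmetric base, keep with
probability equal to the skewing factor, else flip the sign).

## Fitting: direct weighted ML over basis-expanded parameter curves

Each parameter gets a link (identity for `mu` and real-valued `nu`; log
for `sigma`, `tau`, and positive-domain `nu`) and an age basis: constant,
linear, fractional polynomial, or a regression B-spline (cubic by default;
quadratic for the "polynomial spline" option) with interior knots at age
quantiles of the training data. Defaults smooth `mu` (cubic spline, 5
basis functions) and `sigma` (4), keeping `nu`, `tau` constant — which
parameters are smoothed is configurable. All coefficient blocks are
estimated jointly by maximizing the weighted log-likelihood
`sum_i w_i log f(y_i; theta(x_i))` with L-BFGS-B from a warm start
(weighted least squares for `mu`, weighted SD for `sigma`,
family-specific shape starts). The objective trace is recorded per
iteration; convergence is declared when the relative deviance change
drops below 1e-6 (cap 200 iterations), and non-converged models are
barred from ranking and tabulation. Parameters can be pinned at fixed
values (e.g. `nu=0, tau=1` turns a sinh-arcsinh family into its Gaussian
submodel), which is how deliberately misspecified competitors are built
for calibration studies.

Because the spline bases are unpenalized regression splines, the
effective degrees of freedom of a model are exactly its number of free
basis coefficients; `GAIC(k) = -2*loglik + k*edf` therefore needs no
hat-matrix trace. Ties in GAIC (within 1e-9) break by smaller edf, then
by candidate order.

**Support mismatch.** PASE totals are non-negative but every family has
support on the whole line. Models are fitted on raw scores and reported
centiles are floored at zero; with the default calibration this affects
only extreme low centiles at the oldest ages.

## Quantile regression route

For each percentile level tau, coefficients minimize the weighted pinball
loss. The minimization is written as a linear program (residual split
variables; HiGHS solver), so the returned loss is a global optimum — this
is asserted in tests against exhaustive basic-solution enumeration on
small instances. Bases: linear, polynomial of order 2–4, fractional
polynomial (powers from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} on age/10, degree
capped at 2, repeated powers adding log terms), and a smoothed additive
fit: a piecewise-linear curve on ~20 age knots penalized by the total
variation of its slope (an l1 penalty that is itself linear-programmable;
penalty -> infinity recovers the straight line). Observation weights are
used throughout, matching the distributional route; a flag disables them.

Independently fitted quantile curves can cross; crossings are removed by
monotone rearrangement (per-age sorting across levels), which is
idempotent on ordered curves and never increases total pinball loss.

## Cross-validation and selection

Each replicate draws 70% of records *within every year of age*
(round-half-up on the train count; single-record strata are flagged and
sent whole to train), fits every candidate on the train part, and
measures weighted holdout coverage: the fraction of test weight with
score strictly below the fitted 5th and 50th centiles and strictly above
the 95th. Centile curves are evaluated on a 0.25-year grid and
interpolated to subject ages. Per-replicate seeds spawn from one master
seed, and every candidate sees the same splits.

The published procedure states the coverage statistic but not a selection
metric beyond "greater attention to the 5th percentile". The rule used
here is lexicographic: minimize |mean below-P5 − 0.05|; ties within 0.002
break by the 50th, then the 95th, then by fewer failed replicates. This
is an interpretation, and it is deterministic and documented.

## The synthetic cohort and its calibration

The generator emulates the structure of a large national aging-cohort
baseline: ages from a normal(61.6, 9.9) truncated to [45, 85]; 47%
female; interview dates uniform over a calendar year (so seasons are
balanced and season-free by construction); lognormal mean-one inflation
and analytic weights (log-SD 0.35); a mobility-limited subpopulation
(22.6% of records, flagged with gait-aid/ADL indicators, location shifted
−40 points); and 5.9% of records with a missing flag or score.

Scores are drawn from sex-specific ground truths — males SHASHo2, females
SEP4, both with a mild left-heavy asymmetry and linearly declining
location *and* scale:

| sex | family | mu: 45 -> 85 | sigma: 45 -> 85 | nu | tau |
|---|---|---|---|---|---|
| male | SHASHo2 | 209.4 -> 103.8 | 91.4 -> 43.3 | −0.15 | 1.05 |
| female | SEP4 | 170.4 -> 80.2 | 116.2 -> 55.3 | 1.7 | 2.3 |

These were calibrated once so that (i) the true 50th centile falls ~100
points from 45 to 85 (males 195 -> 97, females 170 -> 80), (ii) male
curves dominate female curves at every age and percentile, (iii) marginal
SDs sit near 80/70 with males above females, and (iv) the declining scale
keeps the probability of a negative draw (truncated to 0) below ~4% even
at age 85. The mean/median anchors of real cohorts cannot all be hit
simultaneously by a near-symmetric family over this age distribution; the
median endpoints and decline were prioritized, so marginal means come out
somewhat below the corresponding real-cohort values. Truncation at zero
is the one way generated data depart from the nominal family; it is rare
and concentrated at the oldest ages, so fits of the true family remain
effectively correctly specified.

True parameters and centiles at any (age, sex) are exposed in closed form
(`true_params`, `true_centile`), which is what recovery and coverage
tests compare against. Passing tests therefore demonstrate internal
consistency and estimator correctness under a realistic but idealized
data process — not that real questionnaire data follows these families,
has linear parameter curves, or lacks item-level measurement quirks.

## Instrument scoring

Leisure item: weight × (frequency-midpoint days/week ÷ 7) ×
duration-midpoint hours. Household item: weight × 1{yes}. Work item:
weight × hours/week ÷ 7, only when the work involves standing or walking.
Defaults use the published manual weights (walking 20, light/moderate/
strenuous sport 21/23/23, strength exercise 30, light/heavy housework 25,
repairs 30, lawn work 36, gardening 20, caring 35, work 21) and
conventional midpoints (1.5/3.5/6 days; 0.5/1.5/3/5 hours); both live in
a YAML-serializable config so any revision of the instrument can be
scored. Records with any missing response get an undefined score by
default (they are excluded, mirroring the eligibility rules); a partial
mode sums the present items without imputation. Sitting/sedentary items
never enter the total.

## Problem sizes and numerical choices

* Test suite: distribution oracles at 100k samples (KS) and 1e-6/1e-8/
  1e-10 tolerances as stated above; estimator recovery at n = 10,000
  (constant) and 20,000 (age-varying); CV calibration at n = 20,000 with
  20 replicates; selection trials 20 × 2 replicates at n = 8,000; the
  season-stability check fits four per-season models at n = 400,000 each
  using the generator's own (linear) parameter curves — so pairwise cell
  differences measure seasonal instability rather than spline boundary
  variance — and requires every cell to agree across seasons within
  3 score points.
* `scripts/acceptance.py`: pipeline cohort n = 30,000 with 10 CV
  replicates; season analysis n = 60,000 per season reporting the
  interior (age-65) 5th-percentile range.
* Round-half-up in the 70/30 split; 0.25-year grid for coverage curves;
  table cells floored at 0 and lifted by 1e-9 where flooring creates
  ties; charts rendered with fixed SVG hash salt and no timestamp
  metadata so regeneration is byte-stable.

## Known limitations

* Only 10 of the 30+ screenable four-parameter families are implemented;
  the registry is open to extension.
* Effective df for penalized smoothers is not implemented because the
  default smoothers are unpenalized regression splines; adding a
  penalized smoother would require the hat-trace edf.
* The survey-weighted likelihood treats weights as frequency weights;
  design-based variance (strata/cluster) is out of scope.
* Numeric CDFs (SEP1, SEP2, ST1) make model-based percentile lookup
  slower for those families than for the closed-form ones.
* Season stratification in the generator is a pure null; the pipeline can
  estimate seasonal tables but the synthetic data cannot exhibit a true
  seasonal effect.
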