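# Methods

## The measurement model

`raschdif` analyses ordinal rating-scale data — the motivating use case is a
short psychosomatic-problems scale answered by adolescents, 8 items scored in
5 ordered frequency categories — under the partial credit model (PCM), the
polytomous member of the Rasch family.  For person $n$ with latent location
$\beta_n$ (logits) and item $i$ with location $\delta_i$ and centred
thresholds $\tau_{i1},\dots,\tau_{im_i}$ ($\sum_k \tau_{ik}=0$),

$$
P(X_{ni}=k) \;=\;
\frac{\exp\!\big(\sum_{h\le k}(\beta_n-\delta_i-\tau_{ih})\big)}
     {\sum_{l=0}^{m_i}\exp\!\big(\sum_{h\le l}(\beta_n-\delta_i-\tau_{ih})\big)},
\qquad k = 0,\dots,m_i ,
$$

with the empty sum equal to zero.  Person and item parameters are additive on
one logit scale, the total score is sufficient for $\beta_n$, and the
expected-score curve (EVC) $E[X_{ni}]$ is strictly increasing with slope
equal to the model variance, $dE/d\beta = V[X]$.  Discrimination is never a
free parameter: slope differences between groups are a *diagnostic*
(non-uniform DIF), not a model term.

Parameterisation is partial-credit (per-item thresholds), not rating-scale;
the item location is the mean of the Andrich thresholds.  Disordered
thresholds are reported (`ItemParameters.disordered`) but never reordered.

## Item estimation: pairwise conditional likelihood

Item parameters are estimated by maximising the sum over item pairs of the
conditional likelihood of each pair's responses given the pair's total
score.  Conditioning removes $\beta_n$ exactly, so the estimates do not
depend on the person distribution — the property that justifies equating
across groups and across structurally missing designs.  A pair contributes
only persons who answered both items, which is precisely what resolved,
group-restricted item copies produce.

Practical details:

* Free parameters: $I-1$ locations (sum-to-zero identification) and
  $m_i - 1$ centred thresholds per item; the cumulative parameters
  $\eta_{ik} = \sum_{h\le k}(\delta_i + \tau_{ih})$ are a linear map of the
  free vector, so the analytic gradient (observed minus expected category
  margins per pair) is chained through one precomputed matrix.
* Optimiser: L-BFGS-B, bounds $\pm 30$ logits, up to 500 iterations,
  `gtol = 1e-6`; iteration count and final max-gradient are logged.
  Sufficient pair statistics (one $(m_i{+}1)\times(m_j{+}1)$ contingency
  table per pair) make the objective cost independent of sample size.
* Standard errors come from the inverse curvature of the pairwise objective.
  This is a composite likelihood, so these are approximations (no sandwich
  correction); the Wald statistics attached to DIF magnitudes should be read
  as descriptive effect/noise ratios, not exact tests.
* Connectivity is checked first (items as graph nodes, an edge when at least
  one person answered both); a disconnected design raises an error naming
  the blocks, since no common scale exists.
* Null categories (never observed) are kept by default, with a warning —
  their thresholds are restrained only by the optimiser bounds — or
  collapsed (`FitConfig(null_category="collapse")`), which shifts higher
  scores down and reduces $m_i$.

Person locations given fitted items: Warm's weighted likelihood (WLE,
default) or plain ML, solved by bracketed root finding on the score
function, one solve per distinct (answered-item-set, total-score) pair.
Persons at the minimum or maximum possible total have no finite ML estimate;
they are flagged `extreme`, excluded from residual analysis, class
intervals, group means and PSI.  SE $= 1/\sqrt{\sum_i V_i(\hat\beta)}$.
Under ML the per-person sum of (observed − expected) over answered items is
exactly zero — the total-score constraint that makes artificial DIF
inevitable; WLE departs from it only by the small bias-correction term.

## DIF detection: two-way ANOVA of standardized residuals

Each answered cell yields $z_{ni} = (x_{ni} - E[x_{ni}]) / \sqrt{V[x_{ni}]}$
at the person's estimated location.  Non-extreme persons are partitioned
into $C = 10$ class intervals of approximately equal size along the latent
continuum (quantile rule; remainders go to the lowest intervals; tied
locations are never split — the whole tie group joins the interval where its
first member falls).  Per item, a two-way fixed-effects ANOVA of $z$ with
factors class interval and group separates:

* class-interval main effect — overall misfit along the continuum,
* group main effect — **uniform DIF** (parallel EVC shift),
* group × class interaction — **non-uniform DIF**.

Type II sums of squares are used for the main effects (each adjusted for the
other), the interaction comes from the full factorial, and degrees of
freedom follow the model ranks, so unbalanced or empty cells adjust the df
automatically (with a warning).  Resolved single-group copies get only the
one-way class-interval test — no group contrast exists within one group.

Two guards against over-powered testing in large samples:

* **Sample-size adjustment** (default target $n = 960$): when the effective
  $n$ exceeds the target, each F is multiplied by $n_{960}/n_{\mathrm{eff}}$
  with unchanged numerator df and denominator df recomputed from the target
  $n$ before the p-value is taken.  The exact mechanics of the legacy
  software are undocumented; this rule is simple, auditable, reproduces the
  intent, and can only weaken significance (both raw and adjusted values are
  always reported).
* **Bonferroni**: the family-wise level is $\alpha / n_{\text{tests}}$ with
  3 tests per ordinary item and 1 per resolved copy — 8 items give
  $0.05/24 = 0.002083$; 4 ordinary items plus 8 copies give
  $0.05/20 = 0.002500$ — recomputed at every pass as the roster changes.

Items are flagged when the (adjusted) group or interaction p-value falls
below the level, and ranked by descending group-effect F (interaction F
secondary, item order as the deterministic tie-break).

## Real vs artificial DIF and sequential resolution

Because expected scores must sum to each person's total score, real DIF in
one item *must* induce compensating, opposite-direction artificial DIF
spread over the remaining items.  Resolving everything flagged in one pass
would therefore split items that are merely collateral.  The loop in
`sequential_resolution` instead:

1. fit items → estimate persons → residual ANOVA → Bonferroni level for the
   current test count;
2. if nothing is significant (or everything is resolved): stop;
3. otherwise resolve the *single* worst item — replace it with one copy per
   group, all other groups structurally missing on each copy — and go to 1.

Person estimates are always re-estimated in the current pass, never frozen.
Every pass is recorded in a `ResolutionTrace`; the first pass's flag list is
exactly what simultaneous resolution would have split, so trace vs flags
exposes the artificial-DIF discrepancy directly.  Resolution here is driven
by statistical criteria alone and the outputs are labelled accordingly; in a
real validation study external information about the *source* of DIF should
inform what is resolved, since resolving — like deleting — removes the item
from between-group comparisons and can cost content validity.

DIF magnitude for a resolved item: $\Delta\mathrm{location}$ is the
difference of the copies' locations (uniform DIF, logits);
$\Delta\mathrm{slope}$ is the difference of $V(\beta_{\mathrm{ref}})$
(= EVC slope) at the mean non-extreme person location — chosen as the
reference because data density is maximal there.  Delta-method SEs use the
composite-likelihood covariance.

## Person measurement and reliability

`group_means` averages non-extreme person locations per group (3-decimal
reporting); `difference_delta` reports the change in the between-group
difference across item sets in logits (2 decimals) and as an integer percent
of the baseline.  The Person Separation Index is

$$\mathrm{PSI} = \frac{\widehat{\mathrm{Var}}(\hat\beta) - \overline{SE^2}}
                      {\widehat{\mathrm{Var}}(\hat\beta)} ,$$

truncated to $[0,1]$ — the standard separation-reliability estimator,
analogous to coefficient alpha but valid with missing data (the analogy is
checked against an independently computed alpha on complete simulated data).
Whether extreme persons belong in the group means is not settled by
convention; they are excluded here and the output metadata says so.

## The synthetic-data generator

`SimulationDesign` emulates the target study conditions: 8 items, 5 ordered
categories (higher score = more frequent problems), two groups, person
locations $\mathcal N(\mu_g, 1)$ logits with $\mu_g = 0$ by default; item
locations equispaced on $[-1, 1]$ (centred), centred thresholds equispaced
on $[-1.5, 1.5]$.  Group sizes default to 1000 per group.  Real DIF is
injected by giving the favoured group its own parameters: uniform DIF lowers
that group's item location by exactly $\Delta$ (so it scores higher at the
same $\beta$); non-uniform DIF multiplies that group's threshold spread.  A
per-group mean offset models *impact*, which is not DIF and must not be
flagged — this separation is tested.  The seed fully determines the output,
and a design round-trips through a plain dict/YAML.

What the generator does **not** emulate: survey sampling design and weights,
secular trends across survey waves, incidental (non-structural) missingness
patterns, local dependence between items, and multidimensionality.  Passing
tests therefore demonstrate that the procedure works when the PCM holds and
DIF is the injected kind; they do not certify behaviour under model
violations real questionnaire data may show.

## Problem sizes and numerical choices

Simulation-backed tests and `scripts/acceptance.py` use groups of 1000–2000
persons and 4–25 replicates per claim — sizes at which every tested effect
sits far from its decision boundary (pilot rates 95–100% against ≥90% or
majority criteria) while the whole suite stays fast.  Scenario notes:

* Artificial-DIF induction: $\Delta = 0.5$ in 1 of 8 items; the injected
  item carries the top group F and at least one clean item shows a
  significant opposite-direction effect at unadjusted 0.05.
* The superset (simultaneous vs sequential) demonstration uses two
  same-direction injected items at $\Delta = 1.0$: with a single injected
  item the $n=960$ adjustment deliberately keeps the induced artificial DIF
  below the Bonferroni level, which is the adjustment doing its job.
* Model variance below $10^{-12}$ drops the residual cell with a warning;
  class-interval counts below 2 levels are an error; all-identical residuals
  yield an undefined F reported as missing.
* Convergence: L-BFGS-B stopping at `gtol 1e-6` / `ftol 1e-12` / 500
  iterations, diagnostics logged; person root-finding uses Brent on
  $[-12, 12]$ with automatic bracket expansion.

## Known limitations

* Composite-likelihood SEs are approximate (see above); bootstrap them if
  exact coverage matters.
* The sample-size adjustment is this package's explicit rule, not a
  reimplementation of any legacy software's undocumented one; published F
  values from such software (including its occasionally negative
  "interaction F" entries) are not expected to reproduce to the digit —
  this package's F statistics are standard and non-negative.
* Only one grouping variable is analysed per run; DIF across multiple
  factors (e.g. group × time) requires separate runs.
* Class intervals are formed from estimated locations, so interval
  membership carries estimation noise at small $n$; with 10 intervals the
  procedure is intended for $n$ in the hundreds or more.
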