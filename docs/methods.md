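# Methods

## The model

Each practice is analysed with its own discrete Bayesian belief network over
thirteen variables: nine observed survey predictors, three latent
*intermediate* nodes, and one binary adoption target. The joint distribution
is the product of one conditional probability table (CPT) per variable.

The predictors form three blocks, each feeding one intermediate node:

| block | variables (states, ordered low → high) |
|---|---|
| farm characteristics | farm size (small / medium / large), irrigation system (non-pressurized / pressurized), crop type (annual / perennial) |
| farmer characteristics | income (low / medium / high), education (no / yes college degree), years in farming (≤ / > median 36) |
| engagement | self-certification (no / yes), information sources (≤ / > median 4), consultant (no / yes) |

Continuous survey answers are discretized with cuts at 50 and 200 acres and
50k and 500k US$; the middle category is closed on both sides (a 50-acre or
200-acre farm is "medium", a 50k$ income is "medium"), and median splits put
values equal to the median in the lower state. These boundary conventions are
package choices; the category definitions themselves only fix the open
intervals.

The intermediate nodes exist to keep the target CPT small: with three 3-state
intermediates the target has 27 rows, against 1152 rows for nine direct
parents — the difference between a learnable table and one that overfits any
survey-sized dataset. The intermediates are *artificial*: they have no data
column, no fixed state meaning, and are learned entirely by EM. Their state
count is configurable between 2 and 5 (default 3, keeping the 27-row target).

Cross-edges between predictors are declared explicitly in the structure file.
The default adds farm size → income (large operations earn more) and farm
size → each engagement variable (certification and information use differ
strongly by farm size); any other acyclic cross-edge set can be supplied.
Retargeting the same structure across all eleven practices changes only the
target node.

## Learning

All CPTs are estimated by EM. Each record is expanded into the completions of
its unobserved cells (missing answers plus the three latents, typically 27
completions); the E-step weighs completions by their joint probability under
the current parameters — exact inference per record — and the M-step
renormalizes expected counts plus a symmetric Dirichlet pseudo-count
(default 1, Laplace; 0 gives pure maximum likelihood, in which case a
complete-data fit reduces to frequency counting in a single step).

With a positive pseudo-count this is MAP-EM, whose monotone objective is the
penalized log-likelihood; the implementation asserts that objective
non-decreasing at every iteration, and the raw observed-data log-likelihood
is monotone in the maximum-likelihood case. Convergence is declared at a
relative objective change below 1e-6 or after 200 iterations.

Latent-state symmetry is broken by seeded random Dirichlet initialization
with 5 restarts by default (a deterministic uniform start would leave the
latent states permutation-symmetric forever); the restart with the best final
log-likelihood wins, deterministically for a given seed. Latent states may
come back permuted across seeds — every downstream quantity (target
posteriors, mutual information, intervention deltas) is invariant to such
relabelling, and a test asserts this. Parent configurations never visited
(possible at pseudo-count 0) become uniform rows with a warning. The target
CPT is learned like every other; `em_fit(..., fixed_cpts=...)` pins a
hand-set table instead.

## Validation

Predictive power is scored by repeated random 70/30 train/test splits
(default 5). For each test record all non-missing predictors are entered as
evidence and the most likely target state is the prediction (ties break to
the first declared state, i.e. "no"). The Error Rate alone tracks the
adoption rate — a base-rate predictor errs on exactly min(p, 1−p) of cases —
so the headline measure is the Prediction Improvement Value,
PIV = min(p, 1−p) − ErrorRate, with tiers: negative *not meaningful*,
0–0.10 *reliable*, above 0.10 *especially reliable* (both boundaries assigned
to the lower tier by convention). The adoption rate p is taken from the full
dataset by default, matching the formula's single global quantity; an option
computes it per training split. Records with missing target values are
excluded with a warning; splits lacking a target state in training are
redrawn (at most 10 times). Practices with negative mean PIV are dropped
before sensitivity analysis; only especially reliable practices enter the
policy experiments.

For a target independent of every predictor the model predicts the majority
state everywhere, so each split's PIV equals the full-data rate minus the
test-split rate: the mean PIV is zero *in expectation* and its sign is split
noise. Tests of this case therefore assert "no improvement beyond
split-sampling error" rather than a strict sign.

## Sensitivity and interventions

Mutual information MI(T;X) = Σ P(t,x) log₂ [P(t,x)/(P(t)P(x))] is computed
from the fitted network's joint by exact inference (not the empirical
contingency table), in bits — the base matters only as a common scale factor.
Influence direction is the sign of P(adopt | X = highest state) − P(adopt |
X = lowest state); for 3-state predictors the middle state is ignored, exact
ties are labelled neutral and count as consistent with either sign when
aggregating across practices ("+/−" marks true disagreement).

Interventions are do-operations: the engagement variable's incoming edges are
severed and its marginal fixed — the policy changes behaviour, not beliefs
about farm size (for root levers this coincides with evidence-setting; an
evidence-semantics mode exists for comparison). *Full* mode forces the
engaged state to probability 1; *normalized* mode raises the engaged share by
an absolute increment (default 0.10), applied to the *conditional* engaged
share of the farm type under study so that "10% of this type's farmers
switch"; the unengaged remainder keeps its relative mix, and increments
overflowing probability 1 are capped with a warning. Farm types are entered
as hard evidence on crop type and irrigation; the pooled small/medium size
("S") is the exact event restriction {farm size ≠ large}, renormalized.
Effects are reported as absolute percentage-point changes of the adoption
probability.

## The synthetic generator

The real survey is not deposited, so all end-to-end behaviour is exercised on
samples from a fully specified ground truth over the nine predictors and the
practice targets — deliberately *without* latent nodes, because the
intermediates are a device of the fitted model, not a data-generating claim.
The generator reproduces exactly, by construction of its CPTs:

* the tabulated farm-type composition (8 size × crop × irrigation cells,
  914 farms; the small/medium split within the pooled cells is a free choice,
  set to 60/40, and provably cannot affect any reported margin because small
  and medium always share CPT rows);
* engagement by farm size — self-certification 79% (large) vs 47%
  (small/medium), information sources above median 54% vs 36%, consultant
  38% vs 42%;
* the income anchor P(high income) = 60% given large, 30% given small.

Education (55% college) and years in farming (50/50 by the median-split
definition) are package choices. Practice CPTs use parents (income,
one engagement variable) with additive monotone effects,
P(adopt) = base + step·income + gain·engaged, spreading adoption rates over
roughly 0.06–0.46 and splitting the practices into five strongly
predictable, three moderately predictable, and three rare, weakly-driven
practices — the qualitative tier pattern the analysis is designed to detect.
Missingness is MCAR per column or MAR conditional on farm size (smaller
operations answer fewer questions; farm size itself stays observed, keeping
EM's ignorability assumption intact).

What passing tests on these fixtures do *not* show: the generator encodes no
cross-block dependence beyond farm size, no response-style effects, and
additive (interaction-free) adoption except in the purpose-built
`pp-responsive` scenario, where engagement gains are 0.32 on
perennial-pressurized farms versus 0.06 elsewhere. Real surveys are messier
in all these respects; results on synthetic data validate the machinery, not
substantive conclusions about any real farm population.

Scenario fixtures: `calibrated` (n = 967, MAR missingness, all practices),
`independent-target` (5% adoption, no dependence), `strong-predictor`
(n = 2000, near-deterministic dependence at ~50% adoption), `pp-responsive`
(n = 2000, three practices covering the three engagement channels).

## Numerical choices and problem sizes

Probability rows must normalize within 1e-9; enumeration-oracle comparisons
use 1e-8; XMLBIF round trips are exact (full float repr). Inference is exact
variable elimination with greedy min-size ordering; zero-probability evidence
raises an error rather than returning a silent uniform. A record expanding to
more than 100,000 completions is rejected as a configuration error.

Test and script problem sizes (n = 400–2000 for EM-based checks, 20,000 for
generator CPT recovery, 200 random networks for the inference oracle) are
chosen so the full suite runs in well under a minute of inference-bound work
while keeping sampling error far from each assertion's margin; the stated
recovery bound (0.03 absolute at n = 20,000) corresponds to roughly three
binomial standard errors in the generator's rarest parent configurations.

## Known limitations

Exact inference and record-wise completion limit the approach to networks of
this scale (tens of discrete variables); no structure learning, continuous
nodes, temporal dynamics, or approximate inference. PIV remains biased by the
adoption rate (its ceiling is min(p, 1−p)), so cross-practice comparisons
should read the tier, not the raw value. MI-based sensitivities depend on the
layer structure and variable count and are not comparable across different
network architectures. Intervention results weigh farms equally — adoption
rates, not acreage.
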