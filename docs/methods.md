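# Methods

This note documents the models, estimators and synthetic-data
generator in `effortpath`: what is assumed, which knobs matter, and
what the simulations can and cannot show about real data.

## Choice model

Each trial offers a fixed low-incentive / zero-effort option against a
high-incentive / high-effort option whose incentive and effort levels
(codes 1–3) vary factorially. The decision variable is the
subjective-value difference

```
ΔSV = kBias + benefit − cost
benefit = kR·ΔR            (reward trials)
        = kP·ΔP            (punishment trials; ΔP = loss avoided, in levels)
cost    = (kEp + kFp·F)·ΔE (physical trials)
        = max(kEm − kLm·L, 0)·ΔE (mental trials)
```

and P(high effort) = logistic(ΔSV); the softmax temperature is fixed
at 1 because the sensitivities absorb the scale, and no lapse rate is
modelled. Incentives and efforts enter as level codes, not currency:
per-subject monetary calibration is out of scope, so the low option's
0.5 currency-unit magnitude is carried as metadata only.

Two internal states evolve within a block and reset at its boundaries
(maximal-performance measurements bracket each block, so carry-over is
not modelled):

* **F**, physical fatigue, accrues only from exerted effort:
  F ← F + Ech/(E_max · n_trials). Over a block F runs from 0 to at
  most 1.
* **L**, mental learning / momentary efficiency, accrues 1/n_trials
  per mental trial regardless of the option chosen, so L also spans
  [0, 1].

Normalizing *both* states by block length is a deliberate design
choice: it puts every sensitivity on a comparable O(1) scale, which
makes a single standard-normal prior on the log-parameters meaningful
and keeps the fatigue sensitivity kFp interpretable (the extra cost
per effort level accumulated by the end of a fully exerted block).
The mental cost is clamped at zero so large kLm·L cannot turn effort
into a benefit. Missed choices carry a `missed` flag and are excluded
from likelihoods and modulators; the trial tables default them to the
low-effort option.

SVch, the subjective value of the chosen option (used as an fMRI-style
parametric modulator), is defined with the low option as the zero
benchmark: SVch = ΔSV when the high-effort option was chosen, else 0.
Modulators (Ech, SVch, DT) are z-scored per block with the sample SD;
constant columns degrade to zeros with a warning.

## Fitting: MAP with Laplace evidence

The six non-negative sensitivities are estimated as θ = log k, the
bias on its natural scale. The default prior is N(0, 1) on every
transformed coordinate. The mode is found by L-BFGS from n_restarts
(default 5) seeded starts (first at the prior mean); ties break by
lower objective, then smaller parameter norm; convergence tolerance is
1e−6 on the objective. The evidence is approximated as

```
log p(y) ≈ −NLP(θ*) + (d/2)·log 2π − ½·log |H|
```

with H the finite-difference Hessian of the negative log posterior at
the mode; a non-positive-definite H flags the evidence as unreliable.
This point-estimate-plus-Laplace scheme stands in for a full
variational treatment: all downstream inter-individual analyses use
per-subject point estimates, which MAP supplies. Physical and mental
parameters are fitted jointly on the whole session; kR, kP and kBias
are shared across domains.

Blocks in which one option was chosen on more than 94% of trials are
excluded before fitting (they carry almost no gradient information),
and a subject left without both domains is unfittable.

## Parameter recovery

The recovery study simulates subjects from a population distribution,
refits each, and correlates true with recovered values on the
transformed scale (log for the sensitivities, raw for the bias).
Recovery fits use priors matched to that population distribution —
the self-consistent Bayesian setting for a recovery study — while
`fit_map`'s default prior for data of unknown provenance stays N(0, 1).

The default population distribution is log-normal per sensitivity:
medians 1.0 (kR, kP), 0.8 (kEp), 0.5 (kEm), 0.8 (kFp), 0.3 (kLm) and
log-scale SDs 0.5–0.6, with kBias ~ N(0, 0.3). The medians were set by
a coarse expected-value calculation so that simulated cohorts prefer
the high-effort option at realistic rates (≈50–56% physical, ≈70–76%
mental); the spreads reflect the order-of-magnitude between-subject
heterogeneity typical of effort-discounting cohorts. At 216 trials the
incentive and effort sensitivities recover with r ≳ 0.7–0.9; kFp and
kLm recover weakly (r ≈ 0.1–0.5) because a single session gives each
state only one sweep per block — a genuine identifiability limit of
the design, visible in the confusion matrix, not an estimator defect.

## Synthetic cohort

Latent standardized variables follow the hypothesized causal chain
with Gaussian residuals:

```
plasma lactate → dmPFC/dACC lactate → z(log kEp) → Ech β (dmPFC/dACC)
```

Each configured edge weight equals the population correlation of its
pair (defaults 0.314, 0.317, 0.403; anterior-insula analogues near
zero: plasma → aIns −0.091, kEp → aIns Ech β 0). kEp is the only
behavioral parameter coupled to lactate, encoding the specificity
hypothesis; all other parameters are drawn independently. Lactate is
in arbitrary standardized units — absolute (mM-scale) quantification
is not emulated. Missing lactate values are injected at rates 1/63
(plasma), 2/63 (dmPFC/dACC) and 18/63 (aIns).

Choice proportions (HE/HPE/HME) are **not** drawn from the chain: each
subject's full 216-trial session is simulated from their own
parameters. This keeps proportion-level mediation analyses
non-circular, at a known cost: associations that run through behavior
are attenuated relative to their upstream targets. In particular the
dmPFC/dACC lactate → HPE correlation realizes around −0.2 to −0.25
rather than the configured −0.332 target, since it is bounded by
0.317 × |r(kEp, HPE)| < 0.317 by construction. The target value is
kept in the config as documentation of the intended direction and
rough magnitude.

Deliberation times follow a lognormal model,
DT = exp(b0 − b1·|ΔSV| + ε), ε ~ N(0, σ²), defaults b0 = 0.3,
b1 = 0.15, σ = 0.25 (median ≈ 1.3 s, slower for close calls).

What passing tests on this generator show: the estimators recover the
structure they are pointed at, at the sample sizes used. What they do
not show: anything about measurement noise models of real
spectroscopy or BOLD data (no spectra, no time series, no acquisition
artifacts are simulated), about selection effects in real cohorts, or
about the true functional form of fatigue and learning.

## Between-subject statistics

* **Outlier rule**: a value is excluded when |value − median| >
  3 × sample SD, with the median and SD computed over the variable's
  full non-missing sample (outlier candidates included — so the rule
  is idempotent) and applied per analysis, which is why different
  analyses can retain different Ns.
* **Exclusion boundaries are strict**: a block is dropped above 94%
  one-option choices (51/54 drops, 50/54 stays); a subject is dropped
  above 95% high-effort choices over a task's 108 pooled trials
  (103/108 drops, 102/108 stays). The subject rule is HE-specific:
  uniform low-effort choosers are retained by the rule as stated.
* **Steiger test**: two dependent overlapping correlations r12, r13
  sharing variable 1 are compared via the Fisher-z difference scaled
  by the Dunn–Clark covariance evaluated at the pooled correlation
  r̄ = (r12 + r13)/2. The caller must state the one-tailed direction
  explicitly; there is no default. Because subset re-estimation
  changes the inputs, both entry points exist: `steiger_test` on given
  correlations and `steiger_from_table`, which recomputes all three
  correlations on the common-subject, outlier-filtered subset first.

## Mediation and path models

All variables are standardized over the joint complete cases before
regression, so coefficients are standardized paths and c = c′ + a·b
holds exactly. The mediation verdict follows the joint-significance
rule — significant iff max(p(a), p(b)) < 0.05 and |c′| < |c| — with
the absolute-value comparison because paths may be negative. The
`mediation_p` reported is max(p(a), p(b)); a percentile bootstrap CI
for a·b is provided as a clearly labelled companion. Calibration at
n = 200 (1000 replicates): under b = 0 nulls the rule fires in ~2–4%
of replicates; under a strong chain (a = b = 0.5) in ~96–98%. With
weaker, correlation-sized links (a ≈ 0.31, b ≈ 0.40) the rate drops to
~80–85%, limited by the |c′| < |c| clause's sampling noise rather than
by the significance tests.

The serial path model X1→X2→X3→Y is a just-identified recursive
system, so sequential least squares (X2~X1; X3~X1+X2; Y~X1+X2+X3) is
the exact maximum-likelihood estimator; full-information SEM would add
nothing here and is not implemented. R² is reported per endogenous
node.

## ROI and spectroscopy rules

Masks are boolean grids compared in a common, pre-aligned space;
registration and resampling are out of scope. Density thresholding is
inclusive (≥ cutoff, so "at least 90%" keeps exactly-90% voxels). The
CRLB filter is strict (> 0.5 excluded, 0.5 retained). The CSF
correction rescales a concentration to the tissue-water compartment,

```
corrected = raw × (fGM·43300 + fWM·35880 + fCSF·55556)
                  / (fGM·43300 + fWM·35880)
```

so fCSF = 0 is the identity and the factor grows monotonically with
the CSF fraction. This is the simplest reading consistent with the
three water concentrations; the exact water-scaling convention of
spectral-fitting software varies, so the factor is an isolated,
swappable function.

## Numerical and reproducibility choices

* One master seed drives every pipeline stage through spawned
  substreams; re-running with the same config and seed reproduces all
  artifacts byte-for-byte (fixed float formatting, sorted JSON keys,
  no timestamps).
* Missing values are empty CSV cells, never imputed.
* Simulation sizes in tests and the acceptance script (50 recovery
  subjects, 1000 mediation replicates, 5000-subject fidelity cohorts)
  were chosen so Monte-Carlo error sits well inside each tolerance.
* Significance stars use the conventional thresholds {0.05, 0.01,
  0.001}, uncorrected — the heatmap deliberately performs no
  multiple-comparison correction.

## Known limitations

* The fatigue/learning update rules are plausible defaults, not
  validated forms; alternatives (multiplicative fatigue, per-success
  learning) would need their own recovery analyses.
* kFp and kLm are weakly identified at 216 trials; inferences about
  them at cohort scale need more sessions per subject.
* The generator's missingness is completely at random, whereas real
  missingness (e.g. low spectral quality) may correlate with the very
  quantities under study.
* Monetary amounts, confidence ratings, effort execution dynamics and
  risk attitudes are all outside the model.
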