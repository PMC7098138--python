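# Methods

This note documents the statistical model, the numerical choices, and the
scope of what the test suite does and does not establish.

## Data representation

A VA record is a vector of ternary symptom codes: PRESENT (asked,
affirmed), ABSENT (asked, denied), MISSING (unasked, refused, or "don't
know"). The distinction between ABSENT and MISSING is semantic, not
cosmetic: an absent symptom contributes a factor (1 − p) to the
likelihood, a missing one contributes nothing. All containers, IO and
conversion code preserve the three states; `missing_fraction` and
`coding_audit` exist so a dataset's coding can be inspected before
modelling.

The bundled adult dictionary (`data/adult_symptoms_synthetic.csv`) has
177 symptoms: 14 chronic-condition questions flagged as
health-care-experience (HCE), 20 symptoms dichotomized from continuous
questionnaire fields (durations, counts, weight loss, age), and 143
categorical yes/no symptoms. It is a **synthetic reconstruction**: the
published conversion's exact wording, field names and cutoff values are
not redistributable here, so the bundled table mirrors the structure
(counts, HCE block, cutoff mechanism) with plausible contents. Analyses
of real data should treat it as a template to be checked against the
source codebook. Cutoff rule: a value strictly greater than the cutoff
codes PRESENT; equal or below codes ABSENT; unparseable or blank codes
MISSING. The boundary side is arbitrary but fixed and fixture-tested.

## Conditional-probability matrix (probbase)

`extract_prob_raw` estimates p\_{jc} as the fraction of cause-c training
deaths with symptom j present among those where j is non-missing. Two
numerical guards:

* cells with no non-missing observations fall back to 0.5 (maximal
  ignorance) with a warning — a silent 0 or 1 could veto a cause outright;
* all entries are clamped to [δ, 1 − δ], δ = 10⁻⁴, so no single symptom
  carries infinite evidence.

`bin_to_levels` collapses the matrix onto k ordered level values
(default k = 15). Quantile mode ranks all S×C cells jointly (ties by
average rank, so the result is invariant under cell permutation) and cuts
at equal-count boundaries; fixed mode assigns each cell to the nearest
level on the log scale (thresholds at geometric midpoints). Both are
monotone — binning never inverts the rank order of two cells. The default
level table is a geometric taper from 1 − δ down to δ. The top value is
deliberately capped below 1: a level value of exactly 1 would assign zero
likelihood to any death reporting that symptom absent, and a handful of
such cells can make every cause impossible for a death. The level values
stand in for the classic expert-ranked letter grades, whose numeric
values are not part of this package's contract; the table is overridable.

## Sampler

Model: y\_i | π ~ Categorical(π); s\_ij | y\_i = c ~ Bernoulli(p\_jc) with
missing cells excluded; π = softmax(θ); θ\_c ~ N(0, 1) iid. The prior
mean 0 / scale 1 are configurable; they amount to a weakly informative
logistic-normal prior centred on the uniform CSMF.

One iteration = (a) Gibbs draw of every y\_i from its exact full
conditional (computed in log space from a precomputed n×C log-likelihood
table, so the per-iteration cost is O(nC) regardless of S); (b) joint
Metropolis–Hastings update of θ with an isotropic Normal proposal of
standard deviation `jump_scale`; (c) optionally, when the probbase is
binned and `update_cond_probs` is on, a draw of each level value from its
full conditional — a Beta(A+1, B+1) truncated to the interval between its
ordered neighbours (inverse-CDF sampling; if the truncated mass
underflows, the current value is kept). Defaults follow the standard
schedule: 10,000 iterations, 5,000 burn-in, thin 10, hence 500 retained
draws; `jump_scale` defaults to 0.5.

Per-death posterior probabilities are Rao-Blackwellized: the full
conditional cause distributions are averaged over retained draws rather
than histogramming the y draws (the raw y draws are also retained, and a
test confirms their frequencies agree with the exhaustively enumerated
Bayes-rule posterior when π is held fixed). Randomness is split into
named streams (initialisation, y-updates, θ-updates, level-updates)
derived from one seed, so enabling or disabling one block does not
perturb the others and every run is bit-reproducible.

The acceptance rate is data-dependent. On a 5-cause synthetic problem the
default `jump_scale` 0.5 accepts only ~2% of proposals, because the
posterior on θ is much tighter than the proposal; the sampler-calibration
studies in the test suite therefore run at `jump_scale` 0.1, which yields
~0.3–0.4 acceptance there. On problems with many causes and strong
symptom overlap the default is reasonable. The rate is logged and
reported, never asserted against a fixed value.

Convergence: a Heidelberger–Welch-style stationarity check per cause —
the Cramér–von Mises statistic of the standardized cumulative-sum bridge,
with the long-run variance estimated by batch means (20 batches), against
the 5% critical value 0.461. Only causes with posterior mean CSMF above
0.02 are monitored; small-CSMF chains are the noisiest and a failed flag
is advisory (run more iterations), never fatal.

## Metrics

CCC per cause: (TP\_c/n\_c − 1/N)/(1 − 1/N). Causes with no true deaths in
a test set are excluded from the unweighted mean (their concordance is
0/0; excluding beats fabricating). The floor is −1/(N−1): −1 at two
causes, −0.25 at five.

CSMF accuracy: 1 − Σ|est − true| / (2(1 − min true)). A truth vector
degenerate at a single cause is rejected — the metric is meaningless
there. CCCSMFA = (acc − (1 − e⁻¹))/e⁻¹. The zero point 1 − e⁻¹ ≈ 0.632 is
the large-N limit of the expected accuracy of a uniform guess against
Dirichlet(1) truths; it is a fixed reference value, not "chance
performance" relative to any particular truth — with a uniform true CSMF,
uniform random guessing estimates the CSMF perfectly and CCCSMFA equals 1.
Both facts are asserted in the suite and recomputed by the acceptance
script.

Split summaries report the median and the 2.5th/97.5th empirical
percentiles across splits, with linear interpolation between order
statistics. The uncertainty intervals therefore reflect split-to-split
spread only, not within-split posterior spread.

## Validation design

Each split stratifies deaths by cause into train (default fraction 0.75)
and test partitions, draws a target composition from Dirichlet(α = 1),
and resamples the test partition with replacement to match it (largest-
remainder apportionment, ties to the lowest cause index, so the counts
are exact and deterministic). Recomposition is what stops a trivial
train-CSMF-copying estimator from scoring well. The number of splits
defaults to 500; published results from this package must state the
design values used, since none of them are canonical. Per-split seeds are
derived from the master seed and the (split, condition) pair, so splits
are independent and individually re-runnable; per-split results are
appended to a JSONL log and an interrupted run resumes from it. The
probbase is extracted from the training partition only (an
instrumentation test asserts no test row ever reaches extraction).

## Synthetic generator

The generator draws causes iid from a known CSMF, symptoms from
cause-conditional Bernoullis, then overwrites cells to MISSING uniformly
at random (MCAR) at a configurable rate. The preset mirrors the adult
gold-standard dataset's headline shape: 177 symptoms, 14 HCE flags,
17.8% missing. Probbase cells default to Beta(0.3, 0.3) — U-shaped, a
mix of near-deterministic and uninformative symptoms. HCE cells are
sharpened by multiplying their log-odds by `hce_informativeness`
(default 3), making the HCE block more diagnostic than the rest so that
the with/without-HCE contrast has a known direction by construction.

What the generator does **not** emulate: inter-symptom correlation
within a cause (the data are generated from the classifier's own
conditional-independence assumption), informative missingness, site or
interviewer effects, and free-text narrative features. Passing tests
therefore demonstrate that the machinery is correct and calibrated under
the model's assumptions — not that the classifier performs at any
particular level on real VA data, where all of those violations are
present. Real-data replication additionally requires the published adult
dataset (download from IHME, convert with `vaval convert --raw`,
validate with `vaval validate`), and published conversions differ at
cell level, so only similar — not identical — results should be expected.

## Problem sizes used in the checks

The simulation studies run at deliberately modest sizes chosen once for
the package's own test suite: sampler calibration at C=5, S=30, n=500
(50 replicate datasets; posterior-mean tolerance 0.08 frozen from a
20-replicate pre-study; interval coverage observed 0.93), pipeline
closure at C=6, S=40, n=600 with 20 validation splits and a shortened
1500/500/10 schedule, and the Monte-Carlo limit check at 1000 causes ×
2000 replicates. Larger runs sharpen the same quantities but do not
change any qualitative conclusion.
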