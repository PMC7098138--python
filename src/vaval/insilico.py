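"""Bayesian cause-of-death model and MCMC sampler.

The model couples individual cause assignments with the population
cause-specific mortality fraction (CSMF):

    y_i | pi  ~ Categorical(pi)                      (latent cause of death i)
    s_ij | y_i = c ~ Bernoulli(p_jc)                 (symptom responses)
    pi_c = exp(theta_c) / sum_d exp(theta_d)         (softmax link)
    theta_c ~ Normal(prior_mean, prior_scale^2) iid

MISSING symptom cells are excluded from the likelihood entirely — a missing
response carries no evidence for or against any cause, unlike an ABSENT one
which contributes a (1 - p_jc) factor.

Sampling alternates a Gibbs update of each latent cause y_i from its full
conditional with a joint Metropolis–Hastings update of theta using an
isotropic Normal proposal whose standard deviation is ``jump_scale`` (the
single tuning parameter; it controls the acceptance rate).  When the
conditional-probability matrix is binned to ordered levels, the level
values themselves can optionally be updated each iteration from their full
conditionals, truncated so the strict level ordering is preserved.

Each update block draws from its own named RNG stream derived from the seed,
so toggling one block does not perturb the randomness of the others and
runs are bit-reproducible given (seed, config, data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .probbase import CondProbMatrix, ProbMode, level_indices
from .symptoms import ABSENT, MISSING, PRESENT, SymptomMatrix

# 5% critical value of the Cramer-von Mises statistic (stationarity test).
_CVM_CRIT_05 = 0.461


@dataclass
class InsilicoConfig:
    """Sampler configuration.

    Defaults follow the standard schedule: 10,000 iterations, the first
    5000 discarded as burn-in, every tenth of the second half retained
    (500 draws), Metropolis–Hastings jump scale 0.5.
    """

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    jump_scale: float = 0.5
    seed: int = 0
    update_cond_probs: bool = False
    prior_mean: float = 0.0
    prior_scale: float = 1.0
    #: hold the CSMF fixed at this simplex vector (skip theta updates);
    #: used for validation against the exhaustive Bayes-rule posterior.
    fix_csmf: Optional[np.ndarray] = None

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.jump_scale <= 0:
            raise ValueError("jump_scale must be positive")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")

    @property
    def n_retained(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class PosteriorDraws:
    """Retained MCMC output plus diagnostics.

    csmf_draws: R x C, each row on the simplex.
    individual_probs: n x C Rao-Blackwellized posterior cause probabilities
        (the per-iteration full conditionals averaged over retained draws).
    y_draws: R x n retained latent cause indices.
    acceptance_rate: accepted MH proposals / proposals, post burn-in.
    level_draws: R x k retained level values when adaptive updating is on.
    """

    csmf_draws: np.ndarray
    individual_probs: np.ndarray
    y_draws: np.ndarray
    acceptance_rate: float
    cause_codes: tuple
    death_ids: list
    level_draws: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.csmf_draws.shape[0]

    @property
    def csmf_mean(self) -> np.ndarray:
        return self.csmf_draws.mean(axis=0)

    def csmf_interval(self, level: float = 0.95) -> np.ndarray:
        """(C, 2) equal-tailed credible interval per cause."""
        a = 100 * (1 - level) / 2
        return np.percentile(self.csmf_draws, [a, 100 - a], axis=0).T

    def summary(self) -> dict:
        ci = self.csmf_interval()
        return {
            "csmf_mean": self.csmf_mean.tolist(),
            "csmf_median": np.median(self.csmf_draws, axis=0).tolist(),
            "csmf_ci95_low": ci[:, 0].tolist(),
            "csmf_ci95_high": ci[:, 1].tolist(),
            "cause_codes": list(self.cause_codes),
            "acceptance_rate": self.acceptance_rate,
            "n_retained": self.n_retained,
            "diagnostics": self.diagnostics,
        }


def _ternary_masks(matrix: SymptomMatrix):
    present = (matrix.values == PRESENT).astype(float)
    absent = (matrix.values == ABSENT).astype(float)
    return present, absent


def _log_prob_terms(values: np.ndarray):
    with np.errstate(divide="ignore"):
        return np.log(values), np.log1p(-values)


def individual_posterior(symptoms_row: np.ndarray,
                         probbase: CondProbMatrix,
                         csmf: np.ndarray) -> np.ndarray:
    """Exact posterior over causes for one death given a fixed CSMF.

    Bayes rule with the naive-Bayes likelihood: proportional to
    csmf_c * prod_{j PRESENT} p_jc * prod_{j ABSENT} (1 - p_jc);
    MISSING symptoms contribute no factor.  Computed in log space.
    """
    row = np.asarray(symptoms_row, dtype=np.int8)
    csmf = np.asarray(csmf, dtype=float)
    if row.size != probbase.n_symptoms:
        raise ValueError("symptom row length does not match the probbase")
    if csmf.size != probbase.n_causes:
        raise ValueError("csmf length does not match the probbase causes")
    logp, log1mp = _log_prob_terms(probbase.values)
    with np.errstate(divide="ignore"):
        loglik = (logp[row == PRESENT].sum(axis=0)
                  + log1mp[row == ABSENT].sum(axis=0)
                  + np.log(csmf))
    if np.all(np.isinf(loglik)):
        raise ValueError("all causes have zero posterior probability")
    loglik -= loglik.max()
    post = np.exp(loglik)
    return post / post.sum()


def top_cause(prob_vector: np.ndarray, cause_codes=None):
    """Most probable cause; ties broken by the lowest cause index."""
    idx = int(np.argmax(prob_vector))  # argmax takes the first maximum
    return idx if cause_codes is None else cause_codes[idx]


def _sample_rows_categorical(P: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One categorical draw per row of probability matrix P via inverse CDF."""
    return (P.cumsum(axis=1) > u[:, None]).argmax(axis=1)


def insilico_fit(matrix: SymptomMatrix,
                 probbase: CondProbMatrix,
                 config: InsilicoConfig = None) -> PosteriorDraws:
    """Run the MCMC sampler on a (typically unlabelled) symptom matrix.

    Adaptive updating of the binned level values runs only when
    ``config.update_cond_probs`` is set and the probbase is binned.
    Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = InsilicoConfig()
    if matrix.n_deaths < 1:
        raise ValueError("matrix must contain at least one death")
    if tuple(matrix.dictionary.symptom_ids) != tuple(probbase.symptom_ids):
        raise ValueError("probbase symptoms do not match the matrix dictionary")
    n, C = matrix.n_deaths, probbase.n_causes
    adaptive = config.update_cond_probs and probbase.mode is not ProbMode.RAW

    present, absent = _ternary_masks(matrix)

    # Named independent streams per update block (D-style RNG discipline).
    root = np.random.SeedSequence(config.seed)
    ss_init, ss_y, ss_theta, ss_level = root.spawn(4)
    rng_init = np.random.default_rng(ss_init)
    rng_y = np.random.default_rng(ss_y)
    rng_theta = np.random.default_rng(ss_theta)
    rng_level = np.random.default_rng(ss_level)

    if adaptive:
        lev = level_indices(probbase)              # S x C level index per cell
        k = probbase.level_ref.k
        # count tensors: A[i,c,l] = #present symptoms of death i at level l
        A = np.empty((n, C, k))
        B = np.empty((n, C, k))
        for l in range(k):
            mask = (lev == l).astype(float)
            A[:, :, l] = present @ mask
            B[:, :, l] = absent @ mask
        v = probbase.level_ref.values.copy()
        logv, log1mv = _log_prob_terms(v)
        L = np.tensordot(A, logv, axes=(2, 0)) + np.tensordot(B, log1mv, axes=(2, 0))
    else:
        logp, log1mp = _log_prob_terms(probbase.values)
        L = present @ logp + absent @ log1mp       # n x C fixed log-likelihood

    bad = ~np.isfinite(logsumexp(L, axis=1))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        j = int(np.argmax((matrix.values[i] != MISSING)))
        raise ValueError(
            f"non-finite log-likelihood for death {matrix.death_ids[i]!r} "
            f"(first informative symptom {matrix.dictionary.symptom_ids[j]!r}): "
            "every cause has zero likelihood")

    fixed_pi = config.fix_csmf is not None
    if fixed_pi:
        pi = np.asarray(config.fix_csmf, dtype=float)
        if pi.size != C:
            raise ValueError("fix_csmf length does not match the causes")
        log_pi = np.log(pi)
        theta = None
    else:
        theta = rng_init.normal(config.prior_mean, config.prior_scale, C)
        log_pi = theta - logsumexp(theta)

    R = config.n_retained
    csmf_draws = np.empty((R, C))
    y_draws = np.empty((R, n), dtype=np.int32)
    level_draws = np.empty((R, k)) if adaptive else None
    indiv_accum = np.zeros((n, C))

    accepted = 0
    proposed = 0
    retain_at = set(range(config.burn_in, config.n_iter, config.thin))
    r = 0
    y = None
    prior_var = config.prior_scale ** 2

    for t in range(config.n_iter):
        # --- Gibbs update of latent causes --------------------------------
        W = L + log_pi
        W -= W.max(axis=1, keepdims=True)
        P = np.exp(W)
        P /= P.sum(axis=1, keepdims=True)
        y = _sample_rows_categorical(P, rng_y.random(n))
        counts = np.bincount(y, minlength=C)

        # --- Metropolis-Hastings update of theta (hence pi) ---------------
        if not fixed_pi:
            eps = rng_theta.normal(0.0, config.jump_scale, C)
            log_u = np.log(rng_theta.random())
            theta_prop = theta + eps
            log_pi_prop = theta_prop - logsumexp(theta_prop)
            log_post = (counts @ log_pi
                        - ((theta - config.prior_mean) ** 2).sum() / (2 * prior_var))
            log_post_prop = (counts @ log_pi_prop
                             - ((theta_prop - config.prior_mean) ** 2).sum()
                             / (2 * prior_var))
            if t >= config.burn_in:
                proposed += 1
            if log_u < log_post_prop - log_post:
                theta, log_pi = theta_prop, log_pi_prop
                if t >= config.burn_in:
                    accepted += 1

        # --- adaptive update of ordered level values ----------------------
        if adaptive:
            totA = A[np.arange(n), y, :].sum(axis=0)
            totB = B[np.arange(n), y, :].sum(axis=0)
            us = rng_level.random(k)
            for l in range(k):
                hi = 1.0 if l == 0 else v[l - 1]
                lo = v[l + 1] if l < k - 1 else v[-1] * 1e-2
                dist = beta_dist(totA[l] + 1.0, totB[l] + 1.0)
                c_lo, c_hi = dist.cdf(lo), dist.cdf(hi)
                if c_hi - c_lo > 1e-12:
                    v[l] = float(dist.ppf(c_lo + us[l] * (c_hi - c_lo)))
                    v[l] = min(max(v[l], lo * (1 + 1e-12)), hi * (1 - 1e-12))
            logv, log1mv = _log_prob_terms(v)
            L = (np.tensordot(A, logv, axes=(2, 0))
                 + np.tensordot(B, log1mv, axes=(2, 0)))

        if t in retain_at:
            csmf_draws[r] = np.exp(log_pi)
            y_draws[r] = y
            indiv_accum += P
            if adaptive:
                level_draws[r] = v
            r += 1

    individual_probs = indiv_accum / R
    individual_probs /= individual_probs.sum(axis=1, keepdims=True)
    acc_rate = accepted / proposed if proposed else 1.0

    draws = PosteriorDraws(
        csmf_draws=csmf_draws,
        individual_probs=individual_probs,
        y_draws=y_draws,
        acceptance_rate=acc_rate,
        cause_codes=tuple(probbase.cause_dict.codes),
        death_ids=list(matrix.death_ids),
        level_draws=level_draws,
    )
    if R >= 50:
        flags, warn = convergence_check(draws)
        draws.diagnostics = {"converged": flags, "warning": warn}
    return draws


def acceptance_rate(draws: PosteriorDraws) -> float:
    """Post-burn-in fraction of accepted Metropolis–Hastings proposals."""
    return draws.acceptance_rate


def _spectral_density_zero(x: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means estimate of the spectral density of the chain at zero."""
    m = len(x) // n_batches
    if m < 2:
        n_batches = max(2, len(x) // 2)
        m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return m * means.var(ddof=1)


def heidel_stationarity(x: np.ndarray, crit: float = _CVM_CRIT_05) -> bool:
    """Heidelberger–Welch-style stationarity check on one chain.

    Cramér–von Mises statistic of the standardized cumulative-sum process,
    with the long-run variance estimated by batch means; compared against
    the 5% critical value.  Constant chains pass trivially.
    """
    x = np.asarray(x, dtype=float)
    nn = len(x)
    p0 = _spectral_density_zero(x)
    if p0 <= 0 or not np.isfinite(p0):
        return True
    cs = np.cumsum(x)
    kk = np.arange(1, nn + 1)
    bridge = (cs - kk * x.mean()) / np.sqrt(nn * p0)
    cvm = float((bridge ** 2).mean())
    return cvm < crit


def convergence_check(draws: PosteriorDraws,
                      csmf_threshold: float = 0.02,
                      crit: float = _CVM_CRIT_05):
    """Per-cause stationarity flags for the retained CSMF chains.

    Only causes whose posterior mean CSMF exceeds ``csmf_threshold`` are
    monitored (small-CSMF chains are noisy and the reference behaviour is
    most sensitive there).  Returns (flags, warning): ``flags`` maps cause
    code -> bool (True = stationary or unmonitored), and ``warning`` is True
    when any monitored cause fails.  Advisory, never fatal: a warning means
    more iterations may be needed.
    """
    if draws.n_retained < 50:
        raise ValueError("convergence check needs at least 50 retained draws")
    means = draws.csmf_mean
    flags = {}
    for ci, code in enumerate(draws.cause_codes):
        if means[ci] > csmf_threshold:
            flags[code] = heidel_stationarity(draws.csmf_draws[:, ci], crit)
        else:
            flags[code] = True
    warning = not all(flags.values())
    return flags, warning
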