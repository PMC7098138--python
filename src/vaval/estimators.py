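"""Scikit-learn-style estimator facade over the pipeline.

`InSilicoVA` wraps probbase extraction (fit) and the Bayesian sampler
(predict / predict_proba) in the familiar estimator contract so the
classifier composes with sklearn model-selection tooling.  The method is
transductive at the population level: predicting on a test set runs the
MCMC sampler over that whole set jointly, estimating its CSMF and each
death's posterior cause distribution at once; the posterior draws of the
last prediction are kept on the estimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .insilico import InsilicoConfig, insilico_fit, top_cause
from .probbase import ProbMode, bin_to_levels, default_level_table, \
    extract_prob_raw
from .symptoms import CauseDictionary, SymptomDictionary, SymptomMatrix


def _as_matrix(X, dictionary=None, causes=None, cause_dict=None) -> SymptomMatrix:
    if isinstance(X, SymptomMatrix):
        if causes is not None and X.causes is None:
            return SymptomMatrix(values=X.values, dictionary=X.dictionary,
                                 death_ids=list(X.death_ids),
                                 causes=np.asarray(causes),
                                 cause_dict=cause_dict or X.cause_dict)
        return X
    X = np.asarray(X)
    if dictionary is None:
        dictionary = SymptomDictionary(
            symptom_ids=tuple(f"s{j + 1:03d}" for j in range(X.shape[1])))
    return SymptomMatrix(values=X, dictionary=dictionary,
                         causes=None if causes is None else np.asarray(causes),
                         cause_dict=cause_dict)


class InSilicoVA(ClassifierMixin, BaseEstimator):
    """Bayesian verbal-autopsy cause-of-death classifier.

    Parameters
    ----------
    mode : {"raw", "quantile", "fixed"}
        Conditional-probability extraction mode: raw empirical fractions,
        or quantile / fixed-threshold binning onto ordered levels.
    n_levels : int
        Level count k for the binned modes.
    n_iter, burn_in, thin : int
        MCMC schedule; the defaults retain 500 draws.
    jump_scale : float
        Metropolis–Hastings proposal standard deviation.
    update_cond_probs : bool
        Adaptively re-estimate the binned level values during sampling.
    prior_scale : float
        Prior standard deviation of the softmax CSMF parameters.
    random_state : int
        Sampler seed.

    Attributes
    ----------
    probbase_ : CondProbMatrix
        Conditional-probability matrix extracted from the training data.
    classes_ : ndarray
        Cause codes in dictionary order.
    draws_ : PosteriorDraws
        Posterior draws from the most recent predict/predict_proba call.
    csmf_ : ndarray
        Posterior mean CSMF of the most recent prediction.
    """

    def __init__(self, mode="raw", n_levels=15, n_iter=10_000, burn_in=5_000,
                 thin=10, jump_scale=0.5, update_cond_probs=False,
                 prior_scale=1.0, random_state=0):
        self.mode = mode
        self.n_levels = n_levels
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.jump_scale = jump_scale
        self.update_cond_probs = update_cond_probs
        self.prior_scale = prior_scale
        self.random_state = random_state

    def fit(self, X, y=None):
        """Extract the conditional-probability matrix from labelled deaths.

        X may be a SymptomMatrix (carrying causes when y is None) or a
        ternary ndarray with y the cause labels.
        """
        train = _as_matrix(X, causes=y)
        if train.causes is None:
            raise ValueError("fit requires gold-standard cause labels")
        probbase = extract_prob_raw(train, cause_dict=train.cause_dict)
        mode = ProbMode(self.mode)
        if mode is not ProbMode.RAW:
            probbase = bin_to_levels(
                probbase, levels=default_level_table(self.n_levels), mode=mode)
        self.probbase_ = probbase
        self.classes_ = np.asarray(probbase.cause_dict.codes)
        self.dictionary_ = train.dictionary
        return self

    def _config(self) -> InsilicoConfig:
        return InsilicoConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            jump_scale=self.jump_scale, seed=self.random_state,
            update_cond_probs=self.update_cond_probs,
            prior_scale=self.prior_scale)

    def sample_posterior(self, X):
        """Run the sampler on X and return (and retain) the posterior draws."""
        check_is_fitted(self, "probbase_")
        test = _as_matrix(X, dictionary=self.dictionary_)
        self.draws_ = insilico_fit(test, self.probbase_, self._config())
        self.csmf_ = self.draws_.csmf_mean
        return self.draws_

    def predict_proba(self, X) -> np.ndarray:
        """Posterior cause probabilities per death (n x C)."""
        return self.sample_posterior(X).individual_probs

    def predict(self, X) -> np.ndarray:
        """Most probable cause per death (ties to the lowest cause index)."""
        proba = self.predict_proba(X)
        return np.asarray([top_cause(p, tuple(self.classes_)) for p in proba])
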