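"""Cause-of-death evaluation metrics: CCC, CSMF accuracy, CCCSMFA.

Two families of metric are computed for every validation split:

* Individual-level: chance-corrected concordance (CCC).  For cause c with
  n_c true deaths, CCC_c = (TP_c / n_c - 1/N) / (1 - 1/N), where N is the
  number of causes.  Perfect classification gives 1; classifying every
  death wrongly gives -1/(N-1) — which equals -1 only when N = 2.

* Population-level: CSMF accuracy,
  1 - sum_c |est_c - true_c| / (2 (1 - min_c true_c)), in [0, 1], and its
  chance-corrected linear rescaling CCCSMFA = (acc - (1 - 1/e)) / (1/e).
  The zero point 1 - e^{-1} ≈ 0.632 is the limiting expected CSMF accuracy
  of a uniform guess against Dirichlet(1) truths as the number of causes
  grows; it is a fixed reference, not "random guessing" against any
  particular truth — when the true CSMF is itself uniform, guessing causes
  uniformly at random estimates the CSMF perfectly and CCCSMFA is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .symptoms import CauseDictionary

#: CCCSMFA zero point: limiting E[CSMF accuracy] for uniform guesses
#: against Dirichlet(1) truths as the number of causes -> infinity.
CCCSMFA_ZERO = 1.0 - np.exp(-1.0)


def _check_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"{name} must be a 1-D simplex vector of length >= 2")
    if (v < 0).any() or not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError(f"{name} must be nonnegative and sum to 1")
    return v


def csmf_accuracy(true_csmf: Sequence[float], est_csmf: Sequence[float]) -> float:
    """CSMF accuracy of an estimated cause distribution against the truth.

    1 minus the total absolute error normalized by its maximum possible
    value 2 (1 - min_c true_c); ranges over [0, 1], and equals 1 iff the
    estimate matches the truth exactly.
    """
    t = _check_simplex(true_csmf, "true_csmf")
    e = _check_simplex(est_csmf, "est_csmf")
    if t.size != e.size:
        raise ValueError("true and estimated CSMF must have the same length")
    if np.isclose(t.max(), 1.0):
        raise ValueError("true CSMF degenerate at a single cause")
    return float(1.0 - np.abs(e - t).sum() / (2.0 * (1.0 - t.min())))


def cccsmfa(csmfa: float) -> float:
    """Chance-corrected CSMF accuracy: fixed linear rescaling of accuracy.

    Maps accuracy 1 - e^{-1} (≈0.632) to 0 and perfect accuracy to 1;
    strictly increasing, unbounded below only by the accuracy floor 0
    (which maps to about -1.718).
    """
    return float((csmfa - CCCSMFA_ZERO) / (1.0 - CCCSMFA_ZERO))


def chance_corrected_concordance(assigned: Sequence, truth: Sequence,
                                 causes: CauseDictionary):
    """Per-cause and mean chance-corrected concordance.

    Causes with no true deaths in ``truth`` are excluded (their concordance
    is 0/0); the mean is unweighted over the included causes.  Returns
    (per_cause, mean) where per_cause maps cause code -> CCC_c (NaN when
    excluded).
    """
    assigned = np.asarray(assigned)
    truth = np.asarray(truth)
    if assigned.size == 0:
        raise ValueError("empty assignment vectors")
    if assigned.shape != truth.shape:
        raise ValueError("assigned and truth must have the same length")
    N = len(causes)
    if N < 2:
        raise ValueError("CCC needs at least 2 causes")
    unknown = set(truth) - set(causes.codes)
    if unknown:
        raise ValueError(f"truth causes not in the dictionary: {sorted(unknown)}")
    chance = 1.0 / N
    per_cause = {}
    included = []
    for code in causes.codes:
        mask = truth == code
        n_c = int(mask.sum())
        if n_c == 0:
            per_cause[code] = float("nan")
            continue
        sens = float((assigned[mask] == code).mean())
        ccc = (sens - chance) / (1.0 - chance)
        per_cause[code] = ccc
        included.append(ccc)
    return per_cause, float(np.mean(included))


@dataclass
class MetricResult:
    """Metrics for one validation split."""

    ccc_per_cause: dict
    ccc_mean: float
    csmf_accuracy: float
    cccsmfa: float

    def __post_init__(self):
        n = len(self.ccc_per_cause)
        if n >= 2:
            floor = -1.0 / (n - 1) - 1e-12
            for code, v in self.ccc_per_cause.items():
                if not np.isnan(v) and not (floor <= v <= 1.0 + 1e-12):
                    raise ValueError(f"CCC for cause {code!r} out of range: {v}")
        if not 0.0 <= self.csmf_accuracy <= 1.0:
            raise ValueError("csmf_accuracy must lie in [0, 1]")
        if self.cccsmfa > 1.0 + 1e-12:
            raise ValueError("cccsmfa cannot exceed 1")

    def as_dict(self) -> dict:
        return {
            "ccc_mean": self.ccc_mean,
            "csmf_accuracy": self.csmf_accuracy,
            "cccsmfa": self.cccsmfa,
            "ccc_per_cause": dict(self.ccc_per_cause),
        }


def compute_metrics(assigned, truth, true_csmf, est_csmf,
                    causes: CauseDictionary) -> MetricResult:
    """All split-level metrics from assignments and CSMF estimates."""
    per_cause, mean_ccc = chance_corrected_concordance(assigned, truth, causes)
    acc = csmf_accuracy(true_csmf, est_csmf)
    return MetricResult(ccc_per_cause=per_cause, ccc_mean=mean_ccc,
                        csmf_accuracy=acc, cccsmfa=cccsmfa(acc))


@dataclass
class MetricSummary:
    """Median and 95% uncertainty interval of each metric across splits.

    The UI is the (2.5th, 97.5th) empirical percentile pair of the
    split-to-split distribution (linear interpolation between order
    statistics), matching the median (95% UI) presentation convention.
    """

    median: dict
    ui_low: dict
    ui_high: dict
    n_splits: int

    def __post_init__(self):
        for key in self.median:
            if not (self.ui_low[key] - 1e-12 <= self.median[key]
                    <= self.ui_high[key] + 1e-12):
                raise ValueError(f"UI does not bracket the median for {key!r}")

    def as_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "metrics": {
                key: {"median": self.median[key],
                      "ui95": [self.ui_low[key], self.ui_high[key]]}
                for key in self.median
            },
        }


def summarize_splits(results: Sequence[MetricResult]) -> MetricSummary:
    """Summarize per-split metrics into median and 95% UI."""
    if len(results) == 0:
        raise ValueError("need at least one split result")
    cols = {
        "ccc_mean": [r.ccc_mean for r in results],
        "csmf_accuracy": [r.csmf_accuracy for r in results],
        "cccsmfa": [r.cccsmfa for r in results],
    }
    median, lo, hi = {}, {}, {}
    for key, vals in cols.items():
        q = np.percentile(vals, [50, 2.5, 97.5])  # linear interpolation
        median[key], lo[key], hi[key] = map(float, q)
    return MetricSummary(median=median, ui_low=lo, ui_high=hi,
                         n_splits=len(results))
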