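"""Synthetic verbal-autopsy data generator.

Generates ternary symptom datasets from a known conditional-probability
matrix and a known CSMF, so that every pipeline stage — probbase
extraction, the Bayesian sampler, the metrics, the validation harness —
can be exercised and calibrated against ground truth without any external
download.

The generative model matches the classifier's own assumptions: causes are
drawn iid from the true CSMF; given a death's cause, each symptom is
PRESENT with probability p_jc and ABSENT otherwise, independently across
symptoms; finally each cell is independently overwritten to MISSING at a
fixed rate (missingness completely at random).  The default preset mirrors
the adult gold-standard dataset's headline shape: 177 symptoms of which
the first 14 are flagged as health-care-experience (chronic-condition)
questions, and a 17.8% missing-cell rate.  A U-shaped Beta(0.3, 0.3) prior
on probbase cells mixes informative (near 0/1) and uninformative symptoms;
HCE cells are additionally sharpened toward 0/1 on the log-odds scale so
that withholding them measurably costs the classifier information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .probbase import DELTA, CondProbMatrix, ProbMode
from .symptoms import (ABSENT, MISSING, PRESENT, CauseDictionary,
                       SymptomDictionary, SymptomMatrix)


@dataclass
class SyntheticSpec:
    """Full parameterization of the synthetic generator.

    true_csmf may be an explicit simplex vector or the string
    ``"dirichlet:<alpha>"`` to draw one from a symmetric Dirichlet.
    probbase_gen is either the (a, b) pair of a per-cell Beta distribution
    or an explicit S x C matrix.  hce_informativeness multiplies the
    log-odds of HCE-symptom probbase cells (values > 1 sharpen them
    toward 0/1, making the HCE block more diagnostic than the rest).
    """

    n_causes: int = 10
    n_symptoms: int = 177
    n_deaths: int = 1000
    true_csmf: Union[str, np.ndarray] = "dirichlet:1"
    probbase_gen: Union[tuple, np.ndarray] = (0.3, 0.3)
    missing_rate: float = 0.178
    n_hce: int = 14
    hce_informativeness: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_causes < 2:
            raise ValueError("n_causes must be >= 2")
        if self.n_symptoms < 1:
            raise ValueError("n_symptoms must be >= 1")
        if self.n_deaths < 1:
            raise ValueError("n_deaths must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.n_hce <= self.n_symptoms:
            raise ValueError("n_hce must lie in [0, n_symptoms]")
        if self.hce_informativeness <= 0:
            raise ValueError("hce_informativeness must be positive")
        if isinstance(self.true_csmf, str):
            if not self.true_csmf.startswith("dirichlet:"):
                raise ValueError("true_csmf string must be 'dirichlet:<alpha>'")
            if float(self.true_csmf.split(":", 1)[1]) <= 0:
                raise ValueError("true_csmf Dirichlet alpha must be positive")
        else:
            v = np.asarray(self.true_csmf, dtype=float)
            if v.size != self.n_causes:
                raise ValueError("true_csmf length must equal n_causes")
            if (v < 0).any() or not np.isclose(v.sum(), 1.0):
                raise ValueError("true_csmf must be on the simplex")


def _sharpen(p: np.ndarray, m: float) -> np.ndarray:
    """Multiply the log-odds by m (identity at m = 1)."""
    logit = np.log(p) - np.log1p(-p)
    return 1.0 / (1.0 + np.exp(-m * logit))


def generate(spec: SyntheticSpec):
    """Draw one dataset: (matrix with causes, true probbase, true csmf).

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    C, S, n = spec.n_causes, spec.n_symptoms, spec.n_deaths

    if isinstance(spec.true_csmf, str):
        alpha = float(spec.true_csmf.split(":", 1)[1])
        csmf = rng.dirichlet(np.full(C, alpha))
    else:
        csmf = np.asarray(spec.true_csmf, dtype=float)

    if isinstance(spec.probbase_gen, np.ndarray) or (
            hasattr(spec.probbase_gen, "ndim")):
        P = np.asarray(spec.probbase_gen, dtype=float)
        if P.shape != (S, C):
            raise ValueError("explicit probbase must be n_symptoms x n_causes")
        P = P.copy()
    else:
        a, b = spec.probbase_gen
        P = rng.beta(a, b, size=(S, C))
    P = np.clip(P, DELTA, 1 - DELTA)
    if spec.n_hce and spec.hce_informativeness != 1.0:
        P[: spec.n_hce] = np.clip(
            _sharpen(P[: spec.n_hce], spec.hce_informativeness), DELTA, 1 - DELTA)

    cause_dict = CauseDictionary(
        codes=tuple(f"c{ci + 1:02d}" for ci in range(C)))
    if S == 177 and spec.n_hce == 14:
        # adult-instrument shape: reuse the bundled dictionary so synthetic
        # matrices interoperate with the adult conversion tooling
        from .symptoms import load_adult_dictionary
        dictionary = load_adult_dictionary()
    else:
        hce_flags = np.zeros(S, dtype=bool)
        hce_flags[: spec.n_hce] = True
        dictionary = SymptomDictionary(
            symptom_ids=tuple(f"s{j + 1:03d}" for j in range(S)),
            hce=hce_flags,
        )

    y = rng.choice(C, size=n, p=csmf)
    cells = rng.random((n, S))
    values = np.where(cells < P.T[y], PRESENT, ABSENT).astype(np.int8)
    if spec.missing_rate > 0:
        mask = rng.random((n, S)) < spec.missing_rate
        values[mask] = MISSING

    matrix = SymptomMatrix(
        values=values,
        dictionary=dictionary,
        causes=np.asarray([cause_dict.codes[c] for c in y]),
        cause_dict=cause_dict,
    )
    true_probbase = CondProbMatrix(
        values=P, cause_dict=cause_dict,
        symptom_ids=dictionary.symptom_ids,
        mode=ProbMode.RAW, provenance="synthetic-truth")
    return matrix, true_probbase, csmf


def phmrc_like_preset(seed: int = 0, n_causes: int = 10,
                      n_deaths: int = 2000) -> SyntheticSpec:
    """Spec mirroring the adult gold-standard dataset's headline shape.

    177 symptoms, 14 HCE flags, 17.8% missing cells, U-shaped Beta(0.3, 0.3)
    probbase cells (a mix of strongly informative and uninformative
    symptoms), Dirichlet(1) true CSMF.
    """
    return SyntheticSpec(
        n_causes=n_causes,
        n_symptoms=177,
        n_deaths=n_deaths,
        true_csmf="dirichlet:1",
        probbase_gen=(0.3, 0.3),
        missing_rate=0.178,
        n_hce=14,
        seed=seed,
    )
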