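"""Conditional-probability matrix Pr(symptom | cause) with level binning.

The classifier's knowledge base is an S × C matrix of conditional
probabilities of observing each symptom given each cause, estimated
empirically from labelled training deaths.  Three behaviours are provided,
mirroring the extraction modes of the reference software: the raw empirical
matrix, and two binned variants that collapse the matrix entries into k
ordered levels (k = 15 by default) whose values come from a shared
:class:`LevelTable`.  Binning coarsens the matrix so the sampler is not
overly influenced by estimates close to 0 or 1, and gives the adaptive
level-updating step of the sampler a small ordered parameter set to work on.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .symptoms import ABSENT, MISSING, PRESENT, SymptomMatrix, CauseDictionary

#: Clamp width for raw probabilities: entries live in [DELTA, 1 - DELTA].
DELTA = 1e-4


class ProbMode(str, enum.Enum):
    RAW = "raw"
    QUANTILE_BINNED = "quantile"
    FIXED_BINNED = "fixed"


@dataclass(frozen=True)
class LevelTable:
    """Ordered level values: rank 1 (most probable) down to rank k.

    values must be strictly decreasing, within (0, 1]; k >= 2.
    """

    values: np.ndarray
    labels: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 2:
            raise ValueError("a level table needs k >= 2 levels")
        if not np.all(np.diff(v) < 0):
            raise ValueError("level values must be strictly decreasing")
        if v[0] > 1.0 or v[-1] <= 0.0:
            raise ValueError("level values must lie in (0, 1]")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"L{r}" for r in range(1, v.size + 1)))
        else:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != v.size:
                raise ValueError("labels length must equal k")

    @property
    def k(self) -> int:
        return int(self.values.size)


def default_level_table(k: int = 15) -> LevelTable:
    """Bundled default level table: k strictly decreasing values.

    A geometric taper from (almost) 1 down to DELTA, standing in for the
    ranked letter grades of the classic expert probbase (whose numeric
    values are not part of this package's contract).  The top value is
    capped at 1 - DELTA: a level value of exactly 1 would assign zero
    likelihood to any death reporting that symptom absent.
    """
    values = np.geomspace(1.0, DELTA, k)
    values[0] = 1.0 - DELTA
    return LevelTable(values=values)


@dataclass
class CondProbMatrix:
    """S × C matrix of Pr(symptom present | cause).

    ``mode`` records whether entries are raw empirical fractions or level
    values from ``level_ref``; ``provenance`` identifies the training set.
    """

    values: np.ndarray
    cause_dict: CauseDictionary
    symptom_ids: tuple
    mode: ProbMode = ProbMode.RAW
    level_ref: Optional[LevelTable] = None
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.symptom_ids = tuple(self.symptom_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (symptoms x causes)")
        if self.values.shape != (len(self.symptom_ids), len(self.cause_dict)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.symptom_ids)} symptoms x {len(self.cause_dict)} causes")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("all entries must lie within [0, 1]")
        self.mode = ProbMode(self.mode)
        if self.mode is not ProbMode.RAW:
            if self.level_ref is None:
                raise ValueError("binned matrices must carry a level table")
            extra = set(np.unique(self.values)) - set(self.level_ref.values)
            if extra:
                raise ValueError(
                    f"binned entries outside the level table: {sorted(extra)[:3]}")

    @property
    def n_symptoms(self) -> int:
        return self.values.shape[0]

    @property
    def n_causes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.symptom_ids, name="symptom_id"),
                            columns=list(self.cause_dict.codes))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode.value,
            "provenance": self.provenance,
            "cause_codes": list(self.cause_dict.codes),
            "symptom_ids": list(self.symptom_ids),
            "values": self.values.tolist(),
        }
        if self.level_ref is not None:
            payload["level_values"] = self.level_ref.values.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_csv(cls, path, mode=ProbMode.RAW, level_ref=None) -> "CondProbMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(), symptom_ids=tuple(df.index),
                   cause_dict=CauseDictionary(codes=tuple(df.columns)),
                   mode=mode, level_ref=level_ref)


def extract_prob_raw(train: SymptomMatrix,
                     cause_dict: CauseDictionary = None,
                     provenance: str = "") -> CondProbMatrix:
    """Raw empirical conditional-probability matrix from labelled deaths.

    Entry (j, c) is the fraction of cause-c deaths with symptom j PRESENT
    among those where symptom j is not MISSING (missing cells carry no
    information and are excluded from both numerator and denominator).
    Cells with no non-missing observations fall back to 0.5 (maximal
    ignorance) with a warning.  All entries are clamped to
    [DELTA, 1 - DELTA] so no symptom can ever carry infinite evidence.

    Raises
    ------
    ValueError
        If the matrix has no cause labels, or a dictionary cause has zero
        training deaths (named in the message).
    """
    if train.causes is None:
        raise ValueError("training matrix must carry gold-standard causes")
    if cause_dict is None:
        cause_dict = train.cause_dict
    if cause_dict is None:
        cause_dict = CauseDictionary(codes=tuple(pd.unique(train.causes)))
    S = train.n_symptoms
    C = len(cause_dict)
    values = np.empty((S, C), dtype=float)
    n_empty = 0
    for ci, code in enumerate(cause_dict.codes):
        rows = train.values[train.causes == code]
        if rows.shape[0] == 0:
            raise ValueError(f"cause {code!r} has zero training deaths")
        present = (rows == PRESENT).sum(axis=0)
        informative = (rows != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = present / informative
        empty = informative == 0
        n_empty += int(empty.sum())
        p[empty] = 0.5
        values[:, ci] = p
    if n_empty:
        warnings.warn(
            f"{n_empty} symptom/cause cells had no non-missing training "
            "observations; filled with 0.5", stacklevel=2)
    values = np.clip(values, DELTA, 1.0 - DELTA)
    return CondProbMatrix(values=values, cause_dict=cause_dict,
                          symptom_ids=train.dictionary.symptom_ids,
                          mode=ProbMode.RAW, provenance=provenance)


def bin_to_levels(raw: CondProbMatrix,
                  levels: LevelTable = None,
                  mode: ProbMode = ProbMode.QUANTILE_BINNED) -> CondProbMatrix:
    """Collapse a raw matrix onto the k ordered level values.

    QUANTILE_BINNED ranks all cells jointly (ties by average rank) and cuts
    at the k equal-count quantile boundaries of the empirical distribution;
    FIXED_BINNED assigns each cell to the level whose value is nearest on
    the log scale (fixed thresholds at geometric midpoints between adjacent
    level values).  Both are monotone: the raw rank order of any two cells
    is never inverted by binning.
    """
    mode = ProbMode(mode)
    if raw.mode is not ProbMode.RAW:
        raise ValueError("can only bin a RAW matrix (already binned)")
    if mode is ProbMode.RAW:
        raise ValueError("binning mode must be QUANTILE_BINNED or FIXED_BINNED")
    if levels is None:
        levels = default_level_table()
    k = levels.k
    flat = raw.values.ravel()
    ascending = levels.values[::-1].copy()  # level values, smallest first
    if mode is ProbMode.QUANTILE_BINNED:
        r = rankdata(flat, method="average")  # average rank breaks ties
        # equal-count bins: bin b gets ranks in (b*m/k, (b+1)*m/k]
        bins = np.ceil(r * k / flat.size).astype(int) - 1
        bins = np.clip(bins, 0, k - 1)
    else:
        midpoints = np.sqrt(ascending[:-1] * ascending[1:])
        bins = np.searchsorted(midpoints, flat, side="left")
    binned = ascending[bins].reshape(raw.values.shape)
    return CondProbMatrix(values=binned, cause_dict=raw.cause_dict,
                          symptom_ids=raw.symptom_ids, mode=mode,
                          level_ref=levels, provenance=raw.provenance)


def level_indices(binned: CondProbMatrix) -> np.ndarray:
    """Map each cell of a binned matrix to its level index (0 = rank 1)."""
    if binned.mode is ProbMode.RAW or binned.level_ref is None:
        raise ValueError("level_indices requires a binned matrix")
    lookup = {v: i for i, v in enumerate(binned.level_ref.values)}
    return np.vectorize(lookup.__getitem__)(binned.values).astype(np.int64)
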