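"""Ternary verbal-autopsy symptom data: containers, IO, PHMRC-style conversion.

Verbal-autopsy (VA) records code every symptom question with one of three
states: PRESENT (asked, answered yes), ABSENT (asked, answered no) and
MISSING (not asked, refused, or answered "don't know").  The distinction
between ABSENT and MISSING is semantically load-bearing for the Bayesian
classifier downstream — an ABSENT symptom contributes a ``1 - p`` likelihood
factor while a MISSING one contributes nothing — so this module keeps the
three states explicit end to end and never collapses them.

The central exchange object is :class:`SymptomMatrix`: a deaths × symptoms
grid of ternary codes with optional gold-standard cause labels, tied to a
:class:`SymptomDictionary` describing each column (question text, the
health-care-experience flag, and the dichotomization cutoff for symptoms
derived from continuous questionnaire fields).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Ternary cell codes (int8). No fourth state exists.
PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

_CODES = frozenset({PRESENT, ABSENT, MISSING})

#: Serialization alphabet used by write_va_csv / read_va_csv round trips.
CODE_TO_CHAR = {PRESENT: "Y", ABSENT: "N", MISSING: "."}

#: Default tolerant code map for reading ("dialect" is configurable).
DEFAULT_CODE_MAP = {
    "Y": PRESENT, "y": PRESENT, "1": PRESENT, "yes": PRESENT, "Yes": PRESENT,
    "N": ABSENT, "n": ABSENT, "0": ABSENT, "no": ABSENT, "No": ABSENT,
    ".": MISSING, "": MISSING, "NA": MISSING, "na": MISSING,
    "don't know": MISSING, "Don't Know": MISSING, "dk": MISSING,
    "refused": MISSING, "Refused to Answer": MISSING,
}


@dataclass(frozen=True)
class SymptomDictionary:
    """Ordered description of the symptom columns of a :class:`SymptomMatrix`.

    Parameters
    ----------
    symptom_ids : sequence of str
        Unique short codes, one per column.
    question_text : sequence of str
        Free-text questionnaire wording per symptom.
    hce : ndarray of bool
        Health-care-experience flag (here: history-of-chronic-condition
        questions) per symptom.
    source_fields : sequence of str
        Originating raw questionnaire column names.
    cutoffs : ndarray of float
        Dichotomization threshold for symptoms derived from continuous raw
        fields; NaN for plain categorical symptoms.
    cutoff_units : sequence of str
        Units for the cutoffs ("" when not applicable).
    """

    symptom_ids: tuple
    question_text: tuple = None
    hce: np.ndarray = None
    source_fields: tuple = None
    cutoffs: np.ndarray = None
    cutoff_units: tuple = None

    def __post_init__(self):
        n = len(self.symptom_ids)
        object.__setattr__(self, "symptom_ids", tuple(self.symptom_ids))
        if len(set(self.symptom_ids)) != n:
            raise ValueError("symptom_ids must be unique")
        if self.question_text is None:
            object.__setattr__(self, "question_text", tuple(self.symptom_ids))
        else:
            object.__setattr__(self, "question_text", tuple(self.question_text))
        if self.hce is None:
            object.__setattr__(self, "hce", np.zeros(n, dtype=bool))
        else:
            object.__setattr__(self, "hce", np.asarray(self.hce, dtype=bool))
        if self.source_fields is None:
            object.__setattr__(self, "source_fields", tuple(self.symptom_ids))
        else:
            object.__setattr__(self, "source_fields", tuple(self.source_fields))
        if self.cutoffs is None:
            object.__setattr__(self, "cutoffs", np.full(n, np.nan))
        else:
            object.__setattr__(self, "cutoffs", np.asarray(self.cutoffs, dtype=float))
        if self.cutoff_units is None:
            object.__setattr__(self, "cutoff_units", tuple("" for _ in range(n)))
        else:
            object.__setattr__(self, "cutoff_units", tuple(self.cutoff_units))
        for arr, name in ((self.hce, "hce"), (self.cutoffs, "cutoffs")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} symptoms")
        if len(self.question_text) != n or len(self.source_fields) != n:
            raise ValueError("all dictionary fields must have one entry per symptom")

    def __len__(self) -> int:
        return len(self.symptom_ids)

    @property
    def n_hce(self) -> int:
        return int(self.hce.sum())

    def index_of(self, symptom_id: str) -> int:
        return self.symptom_ids.index(symptom_id)

    def subset(self, keep: np.ndarray) -> "SymptomDictionary":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SymptomDictionary(
            symptom_ids=[self.symptom_ids[i] for i in keep],
            question_text=[self.question_text[i] for i in keep],
            hce=self.hce[keep],
            source_fields=[self.source_fields[i] for i in keep],
            cutoffs=self.cutoffs[keep],
            cutoff_units=[self.cutoff_units[i] for i in keep],
        )


@dataclass(frozen=True)
class CauseDictionary:
    """Cause codes with human-readable labels; N = number of causes."""

    codes: tuple
    labels: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "codes", tuple(self.codes))
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("cause codes must be unique")
        if len(self.codes) < 2:
            raise ValueError("a cause dictionary needs at least 2 causes")
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(str(c) for c in self.codes))
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def n_causes(self) -> int:
        return len(self.codes)

    def index_of(self, code) -> int:
        return self.codes.index(code)


@dataclass
class SymptomMatrix:
    """Deaths × symptoms ternary grid with optional gold-standard causes.

    ``values`` is an int8 array with cells in {PRESENT, ABSENT, MISSING}.
    """

    values: np.ndarray
    dictionary: SymptomDictionary
    death_ids: list = None
    causes: Optional[np.ndarray] = None
    cause_dict: Optional[CauseDictionary] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (deaths x symptoms)")
        bad = ~np.isin(self.values, list(_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid ternary code {self.values[i, j]} at death {i}, symptom {j}"
            )
        if self.values.shape[1] != len(self.dictionary):
            raise ValueError(
                f"{self.values.shape[1]} value columns but dictionary has "
                f"{len(self.dictionary)} symptoms"
            )
        if self.death_ids is None:
            self.death_ids = [f"d{i}" for i in range(self.values.shape[0])]
        self.death_ids = list(self.death_ids)
        if len(self.death_ids) != self.values.shape[0]:
            raise ValueError("death_ids length must equal number of rows")
        if len(set(self.death_ids)) != len(self.death_ids):
            raise ValueError("death_ids must be unique")
        if self.causes is not None:
            self.causes = np.asarray(self.causes)
            if len(self.causes) != self.values.shape[0]:
                raise ValueError("causes length must equal number of deaths")
            if self.cause_dict is not None:
                unknown = set(self.causes) - set(self.cause_dict.codes)
                if unknown:
                    raise ValueError(f"cause codes not in dictionary: {sorted(unknown)}")

    @property
    def n_deaths(self) -> int:
        return self.values.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.values.shape[1]

    def take_deaths(self, idx, death_ids=None) -> "SymptomMatrix":
        """Row subset / resample; repeated indices get suffixed death ids."""
        idx = np.asarray(idx)
        if death_ids is None:
            seen: dict = {}
            death_ids = []
            for i in idx:
                base = self.death_ids[int(i)]
                k = seen.get(base, 0)
                seen[base] = k + 1
                death_ids.append(base if k == 0 else f"{base}#{k}")
        return SymptomMatrix(
            values=self.values[idx],
            dictionary=self.dictionary,
            death_ids=death_ids,
            causes=None if self.causes is None else self.causes[idx],
            cause_dict=self.cause_dict,
        )

    def to_frame(self) -> pd.DataFrame:
        """Ternary grid as a DataFrame of Y/N/. strings (plus cause column)."""
        chars = np.vectorize(CODE_TO_CHAR.get)(self.values) if self.values.size else \
            np.empty(self.values.shape, dtype=object)
        df = pd.DataFrame(chars, columns=list(self.dictionary.symptom_ids),
                          index=pd.Index(self.death_ids, name="death_id"))
        if self.causes is not None:
            df.insert(0, "cause", self.causes)
        return df


def load_adult_dictionary() -> SymptomDictionary:
    """Load the bundled 177-symptom adult dictionary.

    The bundled table is a synthetic reconstruction of an adult VA
    dichotomization map (177 symptoms, of which 14 chronic-condition
    questions carry the HCE flag, and 20 duration/quantity symptoms carry
    numeric cutoffs).  It mirrors the structure of the published adult
    gold-standard conversion but not its exact wording or cutoff values.
    """
    ref = resources.files("vaval.data").joinpath("adult_symptoms_synthetic.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    cutoffs = pd.to_numeric(df["cutoff"], errors="coerce").to_numpy()
    hce = df["hce"].astype(str).str.upper().eq("TRUE").to_numpy()
    return SymptomDictionary(
        symptom_ids=df["symptom_id"].tolist(),
        question_text=df["question_text"].tolist(),
        hce=hce,
        source_fields=df["source_field"].tolist(),
        cutoffs=cutoffs,
        cutoff_units=df["cutoff_units"].tolist(),
    )


def read_va_csv(path, dictionary: SymptomDictionary,
                code_map: dict = None,
                cause_column: str = "cause") -> SymptomMatrix:
    """Read a ternary symptom matrix from CSV.

    The CSV must have a header row; one row per death.  A ``death_id``
    column is used for row identifiers when present, and a cause column
    (default name ``cause``) is carried through as gold-standard labels.
    Cells are decoded with ``code_map`` (default: tolerant Y/N/. dialect).

    Raises
    ------
    ValueError
        If a dictionary symptom column is absent, or a cell value is not in
        the code map (the error names the row and column).
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [s for s in dictionary.symptom_ids if s not in df.columns]
    if missing_cols:
        raise ValueError(f"CSV is missing symptom columns: {missing_cols[:5]}")
    death_ids = df["death_id"].tolist() if "death_id" in df.columns else None
    causes = df[cause_column].to_numpy() if cause_column in df.columns else None
    n = len(df)
    values = np.empty((n, len(dictionary)), dtype=np.int8)
    for j, sid in enumerate(dictionary.symptom_ids):
        col = df[sid].to_numpy()
        for i, raw in enumerate(col):
            try:
                values[i, j] = code_map[raw.strip() if raw not in code_map else raw]
            except KeyError:
                raise ValueError(
                    f"unmappable cell value {raw!r} at row {i}, column {sid!r}"
                ) from None
    return SymptomMatrix(values=values, dictionary=dictionary,
                         death_ids=death_ids, causes=causes)


def write_va_csv(matrix: SymptomMatrix, path) -> None:
    """Serialize a ternary matrix to CSV using the exact Y/N/. alphabet."""
    matrix.to_frame().to_csv(path)


def convert_phmrc_adult(raw_records: pd.DataFrame,
                        dictionary: SymptomDictionary = None,
                        cause_column: str = "gs_text") -> SymptomMatrix:
    """Convert raw adult gold-standard records to a 177-column ternary matrix.

    Categorical source fields map ``Yes``-type answers to PRESENT, ``No``-type
    to ABSENT and refused / don't-know / unasked (blank) to MISSING.
    Continuous source fields are dichotomized at the dictionary cutoff:
    strictly greater than the cutoff → PRESENT, equal or below → ABSENT,
    unparseable or blank → MISSING.  Raw columns not referenced by the
    dictionary are dropped (and logged).  The gold-standard cause column is
    carried through when present.

    Raises
    ------
    ValueError
        If a dictionary source field is absent from the raw records, or a
        continuous field has no cutoff.
    """
    if dictionary is None:
        dictionary = load_adult_dictionary()
    df = raw_records
    n = len(df)
    yes = {"yes", "y", "1"}
    no = {"no", "n", "0"}
    values = np.empty((n, len(dictionary)), dtype=np.int8)
    continuous = ~np.isnan(dictionary.cutoffs)
    for j, src in enumerate(dictionary.source_fields):
        if src not in df.columns:
            raise ValueError(f"raw records are missing source field {src!r}")
        col = df[src]
        if continuous[j]:
            cutoff = dictionary.cutoffs[j]
            if np.isnan(cutoff):
                raise ValueError(
                    f"no cutoff for continuous field {src!r}")  # pragma: no cover
            num = pd.to_numeric(col, errors="coerce")
            out = np.full(n, MISSING, dtype=np.int8)
            out[num.to_numpy() > cutoff] = PRESENT
            out[num.to_numpy() <= cutoff] = ABSENT
            values[:, j] = out
        else:
            s = col.astype(str).str.strip().str.lower()
            out = np.full(n, MISSING, dtype=np.int8)
            out[s.isin(yes).to_numpy()] = PRESENT
            out[s.isin(no).to_numpy()] = ABSENT
            values[:, j] = out
    dropped = [c for c in df.columns
               if c not in set(dictionary.source_fields) and c != cause_column
               and c != "death_id"]
    if dropped:
        logger.info("dropping %d unmapped raw columns (e.g. %s)",
                    len(dropped), dropped[:3])
    causes = df[cause_column].to_numpy() if cause_column in df.columns else None
    death_ids = df["death_id"].tolist() if "death_id" in df.columns else None
    return SymptomMatrix(values=values, dictionary=dictionary,
                         death_ids=death_ids, causes=causes)


def strip_hce(matrix: SymptomMatrix) -> SymptomMatrix:
    """Drop all HCE-flagged symptom columns; death order untouched.

    Used for the "no HCE" arm of the validation contrast, where the
    health-care-experience questions (chronic-condition history) are withheld
    from the classifier.
    """
    keep = ~matrix.dictionary.hce
    if not keep.any():
        raise ValueError("stripping HCE symptoms would leave zero columns")
    if keep.all():
        return matrix
    return SymptomMatrix(
        values=matrix.values[:, keep],
        dictionary=matrix.dictionary.subset(keep),
        death_ids=list(matrix.death_ids),
        causes=matrix.causes,
        cause_dict=matrix.cause_dict,
    )


def missing_fraction(matrix: SymptomMatrix) -> float:
    """Fraction of MISSING cells over all cells. Errors on an empty matrix."""
    if matrix.values.size == 0:
        raise ValueError("missing_fraction is undefined for an empty matrix")
    return float((matrix.values == MISSING).mean())


def coding_audit(matrix: SymptomMatrix) -> pd.DataFrame:
    """Per-symptom counts of PRESENT / ABSENT / MISSING cells.

    Returns a DataFrame indexed by symptom id with columns
    ``present``, ``absent``, ``missing``; each row sums to the death count.
    """
    v = matrix.values
    return pd.DataFrame(
        {
            "present": (v == PRESENT).sum(axis=0),
            "absent": (v == ABSENT).sum(axis=0),
            "missing": (v == MISSING).sum(axis=0),
        },
        index=pd.Index(matrix.dictionary.symptom_ids, name="symptom_id"),
    )
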