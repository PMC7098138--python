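import numpy as np
import pandas as pd
import pytest

from vaval import (ABSENT, MISSING, PRESENT, CauseDictionary,
                   SymptomDictionary, SymptomMatrix, load_adult_dictionary)


@pytest.fixture(scope="session")
def adult_dictionary():
    return load_adult_dictionary()


@pytest.fixture
def small_dictionary():
    return SymptomDictionary(
        symptom_ids=("s1", "s2", "s3"),
        hce=np.array([True, False, False]),
    )


@pytest.fixture
def toy_matrix(small_dictionary):
    """4 deaths x 3 symptoms with both causes represented."""
    values = np.array([
        [PRESENT, ABSENT, MISSING],
        [ABSENT, ABSENT, PRESENT],
        [PRESENT, PRESENT, PRESENT],
        [MISSING, ABSENT, ABSENT],
    ], dtype=np.int8)
    causes = np.array(["ca", "cb", "ca", "cb"])
    return SymptomMatrix(values=values, dictionary=small_dictionary,
                         causes=causes,
                         cause_dict=CauseDictionary(codes=("ca", "cb")))


def make_raw_records(dictionary, n=1, **overrides):
    """Raw questionnaire rows with every source field blank (-> MISSING),
    selectively overridden per source field."""
    data = {src: [""] * n for src in dictionary.source_fields}
    data["gs_text"] = [f"cause{i % 2}" for i in range(n)]
    for key, vals in overrides.items():
        data[key] = vals if isinstance(vals, list) else [vals] * n
    return pd.DataFrame(data)


@pytest.fixture
def raw_records_factory(adult_dictionary):
    def factory(n=1, **overrides):
        return make_raw_records(adult_dictionary, n=n, **overrides)
    return factory
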