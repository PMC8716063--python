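import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import cherry_tree, linear_tree, star_tree  # noqa: E402

from clonex.trees import PatientSample  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mixed_cohort():
    """15-patient cohort shaped like a published AML result row: the pair
    (FLT3, NRAS) occurs in 8 informative patients (7 exclusive, 1
    co-occurring), 3 linear and 4 star patients."""
    patients = []
    i = 0
    for _ in range(7):  # informative, exclusive
        t = cherry_tree(f"p{i:02d}", [f"X{i}"], ["FLT3"], ["NRAS"])
        patients.append(PatientSample.from_trees(t.patient_id, [t]))
        i += 1
    # informative, co-occurring: pair on one branch, second branch distinct
    t = cherry_tree(f"p{i:02d}", [f"X{i}"], ["FLT3", "NRAS"], [f"Y{i}"])
    patients.append(PatientSample.from_trees(t.patient_id, [t]))
    i += 1
    for _ in range(3):  # linear
        t = linear_tree(f"p{i:02d}", [f"X{i}", "FLT3", "NRAS"])
        patients.append(PatientSample.from_trees(t.patient_id, [t]))
        i += 1
    for _ in range(4):  # star
        t = star_tree(f"p{i:02d}", [f"X{i}", "FLT3", "NRAS"])
        patients.append(PatientSample.from_trees(t.patient_id, [t]))
        i += 1
    return patients
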