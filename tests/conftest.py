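import numpy as np
import pandas as pd
import pytest

from concord import solve_components_obj1, solve_components_obj2


def make_readings(subject_labels, objective=1, classification="Shape"):
    """Build a long-format reading table from per-subject label dicts.

    Each element of ``subject_labels`` maps reader roles to labels:
    objective 1 -> {"device": lbl, "radiologists": [lbl, ...]};
    objective 2 -> {"device": lbl, "seniors": [...], "juniors": [...]}.
    """
    rows = []
    for i, labels in enumerate(subject_labels):
        sid = f"P{i + 1:03d}"
        rows.append((sid, "AI", "device", classification, labels["device"]))
        if objective == 1:
            for j, v in enumerate(labels["radiologists"]):
                rows.append((sid, f"R{j + 1:02d}", "radiologist", classification, v))
        else:
            for j, v in enumerate(labels["seniors"]):
                rows.append((sid, f"S{j + 1:02d}", "senior", classification, v))
            for j, v in enumerate(labels["juniors"]):
                rows.append((sid, f"J{j + 1:02d}", "junior", classification, v))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "reader_id", "reader_role", "classification", "value"],
    )


@pytest.fixture(scope="session")
def components1_rho01():
    return solve_components_obj1(0.1, 10)


@pytest.fixture(scope="session")
def components1_rho03():
    return solve_components_obj1(0.3, 10)


@pytest.fixture(scope="session")
def components2_rho01():
    return solve_components_obj2(0.1, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(20211104)
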