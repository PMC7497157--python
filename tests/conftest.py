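import numpy as np
import pytest

from osteosex import (
    MeasurementRecord,
    ReferenceSample,
    default_population,
    generate_reference_sample,
)


def make_sample(values_f, values_m, variables=("x",)):
    """Build a small reference sample from per-sex value rows."""
    records = []
    for k, row in enumerate(np.atleast_2d(np.asarray(values_f, dtype=float))):
        records.append(
            MeasurementRecord(
                id=f"F{k}", sex="F",
                measurements={v: float(x) for v, x in zip(variables, row)},
            )
        )
    for k, row in enumerate(np.atleast_2d(np.asarray(values_m, dtype=float))):
        records.append(
            MeasurementRecord(
                id=f"M{k}", sex="M",
                measurements={v: float(x) for v, x in zip(variables, row)},
            )
        )
    return ReferenceSample(records=records, variables=list(variables))


@pytest.fixture
def toy_1d():
    """1-D toy: female values {1,2,3}, male {5,7,9}; raw midpoint 4.5."""
    return make_sample([[1], [2], [3]], [[5], [7], [9]])


@pytest.fixture(scope="session")
def study_sample():
    """Synthetic sample under the study conditions (48 F / 36 M, published
    humeral moments)."""
    return generate_reference_sample(default_population(), seed=20)


@pytest.fixture(scope="session")
def humeral_variables():
    return ["head_diameter", "epicondylar_breadth"]
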