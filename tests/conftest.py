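import math

import numpy as np
import pytest

from nanoprune.core_data import BioassayRecord, ResponseSeries


@pytest.fixture
def log_series():
    """Exact line in ln c: y = -2 ln c + 5 at c = 1, e, e^2."""
    c = np.array([1.0, math.e, math.e**2])
    return ResponseSeries(
        "NM", 49, "reproduction", c, np.array([5.0, 3.0, 1.0]),
        np.full(3, np.nan), np.ones(3, int),
    )


@pytest.fixture
def logistic_series():
    """Noiseless logistic2 with EC50 = 650, slope = 3, y0 = 500."""
    c = np.array([0.0, 100.0, 320.0, 640.0, 1000.0, 3200.0])
    y = np.empty_like(c)
    y[0] = 500.0
    y[1:] = 500.0 / (1.0 + np.exp(3.0 * (np.log(c[1:]) - math.log(650.0))))
    return ResponseSeries("NM", 21, "reproduction", c, y, np.full(6, np.nan), np.ones(6, int))


def make_records(material, counts_by_conc, day=49, endpoint="reproduction"):
    out = []
    for conc, counts in counts_by_conc.items():
        for rep, n in enumerate(counts, start=1):
            out.append(
                BioassayRecord(
                    material=material, concentration=conc, replicate=rep,
                    day=day, endpoint=endpoint, count=n,
                )
            )
    return out
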