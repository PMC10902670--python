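import pandas as pd
import pytest

import cytorisk as cr


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across tests (default design,
    reduced sequencing depth for speed)."""
    spec = cr.CohortSpec(cells_per_patient=800, seed=11)
    events, cytokines, outcomes = cr.generate_cohort(spec)
    return spec, events, cytokines, outcomes


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    _, events, cytokines, outcomes = small_cohort
    gated = cr.gate_events(events)
    return cr.build_feature_table(gated, cytokines, outcomes)


@pytest.fixture()
def tiny_events():
    """Two patients, two hand-written cells each, one marker of interest."""
    import numpy as np

    # raw intensities chosen so arcsinh(x/5) is exactly 1.0 and 3.0
    lo, hi = 5 * np.sinh(1.0), 5 * np.sinh(3.0)
    rows = []
    for pid in ("P01", "P02"):
        for v in (lo, hi):
            row = {"patient_id": pid, "subset": "NK(CD56bright)"}
            for m in cr.synthetic.P.ALL_MARKERS:
                row[m] = v
            rows.append(row)
    return pd.DataFrame(rows)
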