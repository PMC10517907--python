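import numpy as np
import pandas as pd
import pytest

from placenta_dwi import io, synth
from placenta_dwi.models import PROTOCOL_BVALUES


@pytest.fixture(scope="session")
def bvalues():
    return np.array(PROTOCOL_BVALUES)


@pytest.fixture(scope="session")
def adverse_params():
    """Adverse-group mean parameters on fitting scales."""
    t = synth.TABLE_PARAMS["adverse"]
    return {
        "f": t["f"][0] / 100,
        "D": t["D"][0] * 1e-3,
        "Dstar": t["Dstar"][0] * 1e-3,
        "DDC": t["DDC"][0] * 1e-3,
        "Alpha": t["Alpha"][0],
        "ADC": t["ADC"][0] * 1e-3,
    }


@pytest.fixture(scope="session")
def non_adverse_params():
    t = synth.TABLE_PARAMS["non_adverse"]
    return {
        "f": t["f"][0] / 100,
        "D": t["D"][0] * 1e-3,
        "Dstar": t["Dstar"][0] * 1e-3,
        "DDC": t["DDC"][0] * 1e-3,
        "Alpha": t["Alpha"][0],
        "ADC": t["ADC"][0] * 1e-3,
    }


@pytest.fixture()
def small_series(bvalues):
    """A tiny spatially-constant mono-exponential DWI series."""
    from placenta_dwi.models import mono_signal

    sig = mono_signal(1.0e-3, 100.0, bvalues)
    vol = np.broadcast_to(sig, (3, 3, 2, bvalues.size)).copy()
    return io.DWISeries(vol, bvalues, (2.0, 2.0, 4.0))


@pytest.fixture(scope="session")
def default_cohort():
    return synth.simulate_cohort(seed=42)


@pytest.fixture()
def table1_cohort():
    """A cohort whose categorical columns reproduce the published 2x2
    contingency tables (counts only; continuous columns are fillers)."""
    rows = []
    counts = {
        "adverse": {"n": 20, "vaginal": 4, "preterm": 11, "male": 6},
        "non_adverse": {"n": 40, "vaginal": 19, "preterm": 6, "male": 16},
    }
    i = 0
    for g, c in counts.items():
        for j in range(c["n"]):
            rows.append({
                "subject_id": f"P{i:03d}",
                "group": g,
                "delivery_route": "vaginal" if j < c["vaginal"] else "cesarean",
                "preterm": "yes" if j < c["preterm"] else "no",
                "neonatal_sex": "male" if j < c["male"] else "female",
            })
            i += 1
    return io.CohortTable(pd.DataFrame(rows))
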