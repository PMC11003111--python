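import numpy as np
import pandas as pd
import pytest

import adhertraj as at


@pytest.fixture(scope="session")
def small_cohort():
    """500-patient synthetic cohort with the default covariate effects."""
    cfg = at.default_config(n_patients=500, seed=3)
    patients, truth = at.generate_cohort(cfg)
    visits, censoring = at.generate_follow_up(patients, truth, cfg)
    return cfg, patients, truth, visits, censoring


@pytest.fixture(scope="session")
def recovery_panel():
    """Panel drawn directly from the default 3-group censored-normal model."""
    cfg = at.default_config(n_patients=1000, covariate_effects={})
    panel, truth = at.simulate_panels(cfg, seed=11)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def fitted_3group(recovery_panel):
    cfg, panel, truth = recovery_panel
    model = at.fit_gbtm(panel, 3, (0, 2, 2), seed=5, n_restarts=2)
    return cfg, panel, truth, model


def single_patient_visits(pid, reg_dates, therapy="TAM"):
    return pd.DataFrame(
        {
            "patient_id": pid,
            "visit_date": list(reg_dates),
            "aet_reported": 1,
            "therapy": therapy,
        }
    )


def no_censoring():
    return pd.DataFrame(columns=["patient_id", "event_date", "reason"])


def day_resolution_pdc(reg_dates, index, end, interval=182, supply=182, cap=182,
                       min_last=14):
    """Brute-force per-day supply simulation (independent oracle)."""
    import math

    regs = set(d for d in reg_dates if d < end)
    bal = 0
    covered = np.zeros(max(end - index, 0), dtype=bool)
    for day in range(index, end):
        if day != index and (day - index) % interval == 0:
            bal = min(bal, cap)
        if day in regs:
            bal += supply
        if bal > 0:
            covered[day - index] = True
            bal -= 1
    rows = []
    n_int = math.ceil((end - index) / interval)
    for t in range(n_int):
        a, b = t * interval, min((t + 1) * interval, end - index)
        denom = b - a
        if denom < min_last and t == n_int - 1 and t > 0:
            break
        rows.append((t, int(covered[a:b].sum()), denom))
    return rows
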