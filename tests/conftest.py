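import dataclasses

import pandas as pd
import pytest

from egfr_traj import GeneratorConfig, build_cohort, generate_cohort
from egfr_traj.cohort import pre_t0_points


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by unit tests: generated once,
    deterministic, with its built analysis table and pre-T0 eGFR points."""
    cfg = dataclasses.replace(GeneratorConfig(), n_patients=400, seed=101)
    synth = generate_cohort(cfg)
    cohort, exclusions = build_cohort(synth.measurements, synth.patients)
    points = pre_t0_points(synth.measurements, synth.patients, cohort)
    return {
        "config": cfg,
        "synth": synth,
        "cohort": cohort,
        "exclusions": exclusions,
        "points": points,
    }


def toy_measurements(rows):
    """rows: (patient_id, date, analyte, value) tuples -> measurements frame."""
    return pd.DataFrame(rows, columns=["patient_id", "date", "analyte", "value"])


def toy_patients(ids, birth="1935-06-15", sex="M", race="white", death=None, **flags):
    from egfr_traj.synthetic import COMORBIDITIES

    df = pd.DataFrame(
        {
            "patient_id": ids,
            "birth_date": birth,
            "sex": sex,
            "race": race,
            "death_date": death,
        }
    )
    for c in COMORBIDITIES:
        df[c] = flags.get(c, 0)
    return df
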