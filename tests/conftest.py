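import pandas as pd
import pytest

from oatrisk.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (deterministic)."""
    config = SimulationConfig(n_patients=800, seed=7)
    patients, rx, adm, deaths, truth = generate_cohort(config)
    return {
        "config": config,
        "patients": patients,
        "prescriptions": rx,
        "admissions": adm,
        "deaths": deaths,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_run(small_cohort):
    """Pipeline run (no model fits) on the shared cohort."""
    from oatrisk.pipeline import RunConfig, run_pipeline

    return run_pipeline(
        small_cohort["patients"],
        small_cohort["prescriptions"],
        small_cohort["admissions"],
        small_cohort["deaths"],
        RunConfig(fit_models=False),
    )


@pytest.fixture()
def toy_code_list():
    from oatrisk.ascertain import CodeList

    return CodeList(
        pd.DataFrame(
            {
                "code": ["T40", "T43", "X42", "X44", "Z915", "BUP-PATCH-5"],
                "system": ["ICD10", "ICD10", "ICD10", "ICD10", "READ", "PRODUCT"],
                "category": [
                    "nonfatal_overdose",
                    "nonfatal_overdose",
                    "fatal_overdose",
                    "fatal_overdose",
                    "overdose_history",
                    "analgesia_exclusion",
                ],
            }
        )
    )
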