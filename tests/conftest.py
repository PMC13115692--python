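import numpy as np
import pandas as pd
import pytest

from riskhapscan.io import CohortTable, MarkerMap, PhasedHaplotypeSet


def make_haps(alleles, positions=None, chromosome="3", start=1_000_000,
              spacing=10_000):
    """Small PhasedHaplotypeSet from a 0/1 matrix (rows = haplotypes)."""
    A = np.asarray(alleles, dtype=np.uint8)
    h, m = A.shape
    if positions is None:
        positions = start + spacing * np.arange(m)
    mm = MarkerMap(
        [f"M{j}" for j in range(m)], chromosome, positions,
        ["A"] * m, ["G"] * m,
    )
    ids = [(f"D{i + 1}", s) for i in range(h // 2) for s in (1, 2)]
    return PhasedHaplotypeSet(ids, A, mm)


def make_cohort(rows):
    """CohortTable from a list of dicts with sensible defaults."""
    defaults = dict(
        status="control", sex="F", lineage="show", cohort_label="GWAS",
        age_onset_years=np.nan, age_last_followup_years=9.0,
        age_gonadectomy_years=np.nan, gonadal_status="intact",
    )
    recs = []
    for i, r in enumerate(rows):
        rec = dict(defaults, dog_id=f"D{i + 1}")
        rec.update(r)
        recs.append(rec)
    return CohortTable(pd.DataFrame(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated cohort under the default study conditions."""
    from riskhapscan.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=11))
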