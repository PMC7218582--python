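import math

import numpy as np
import pandas as pd
import pytest

from lbqc.io import (
    Buffer,
    CountTable,
    Kit,
    Role,
    SampleRecord,
    to_proportions,
)
from lbqc.simulate import SimConfig, generate_cohort


@pytest.fixture
def toy_counts() -> CountTable:
    """3 OTUs x 3 samples with simple integer counts."""
    return CountTable(
        pd.DataFrame(
            [[2, 0, 5], [0, 0, 3], [2, 0, 2]],
            index=["OTU_1", "OTU_2", "OTU_3"],
            columns=["S1", "S2", "S3"],
        )
    )


def make_records(
    n_spec=3, n_ntc=2, copies=(1000.0, 2000.0, 100.0)
) -> list[SampleRecord]:
    recs = [
        SampleRecord(
            sample_id=f"S{i + 1}",
            role=Role.SPECIMEN,
            copies_per_ul=copies[i % len(copies)],
            age_days=30.0,
            run_id="run1",
            well=f"A{i + 1}",
            repeat_group=f"G{i + 1}",
            buffer=Buffer.PRIMESTORE,
            kit=Kit.KIT_QS,
        )
        for i in range(n_spec)
    ]
    recs += [
        SampleRecord(
            sample_id=f"N{i + 1}",
            role=Role.NTC,
            copies_per_ul=0.0,
            age_days=math.nan,
            run_id="run1",
            well=f"B{i + 1}",
            buffer=Buffer.PRIMESTORE,
            kit=Kit.KIT_QS,
        )
        for i in range(n_ntc)
    ]
    return recs


@pytest.fixture(scope="session")
def default_cohorts():
    """Ten default-parameter cohorts (seeds 1..10), shared across tests."""
    out = []
    for seed in range(1, 11):
        out.append(generate_cohort(SimConfig(seed=seed)))
    return out


def specimen_ntc_subset(table, records):
    keep = [r.sample_id for r in records if r.role in (Role.SPECIMEN, Role.NTC)]
    sub = table.select_samples(keep)
    recs = [r for r in records if r.sample_id in keep]
    return sub, recs
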