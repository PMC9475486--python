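import numpy as np
import pandas as pd
import pytest

import cdrstraj as ct
from cdrstraj.cohort import ITEM_COLS, META_COLS, Cohort
from cdrstraj.mixture import BaselineMixture
from cdrstraj.model import PipelineConfig, TreatmentCourseModel
from cdrstraj.scale import ITEM_MAXES


def spread_items(total: int) -> list[int]:
    """Deterministic 17-item allocation summing exactly to ``total``."""
    scores = [1] * 17
    excess = total - 17
    i = 0
    while excess > 0:
        if scores[i] < ITEM_MAXES[i]:
            scores[i] += 1
            excess -= 1
        i = (i + 1) % 17
    return scores


def make_cohort(triples, arm="fluoxetine", items_fn=spread_items) -> Cohort:
    """Cohort from (baseline, mid, end) total triples."""
    rows = []
    for i, (b, m, e) in enumerate(triples):
        rec = {
            "patient_id": f"p{i:03d}",
            "arm": arm,
            "age": 14.0 + (i % 5),
            "sex": "female" if i % 2 else "male",
            "race": ("white", "black", "other")[i % 3],
        }
        for visit, total in (("baseline", b), ("mid", m), ("end", e)):
            rec.update(dict(zip(ITEM_COLS[visit], items_fn(total))))
        rows.append(rec)
    return Cohort(pd.DataFrame(rows, columns=META_COLS + [c for v in ITEM_COLS.values() for c in v]))


def fixed_mixture(boundary: int = 55) -> BaselineMixture:
    return BaselineMixture(
        weights=(0.42, 0.58), means=(49.0, 65.0), sds=(4.5, 5.0),
        boundary=boundary, log_likelihood=0.0,
    )


@pytest.fixture(scope="session")
def training_cohort():
    cfg = ct.default_configs()["training_fluoxetine"]
    return ct.generate_cohort(cfg, seed=17)


@pytest.fixture(scope="session")
def fitted(training_cohort):
    model = TreatmentCourseModel(training_cohort, PipelineConfig(seed=17))
    return model.fit()
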