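"""Shared fixtures: small synthetic cohorts and derived training matrices."""

from __future__ import annotations

import numpy as np
import pytest

from ecgdann.cli import LABEL_INDEX, assemble_dataset
from ecgdann.features_balance import smote_balance
from ecgdann.synthetic_ecg import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six records per domain, 30 s each — enough beats to train on."""
    spec = SyntheticCohortSpec(n_records=6, duration_s=30.0, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    """(source, target) matrices from the small cohort, Q/degenerate dropped."""
    src = [b.record for b in small_cohort if b.domain == 0]
    tgt = [b.record for b in small_cohort if b.domain == 1]
    Xs, Fs, ys, table_s = assemble_dataset(src)
    Xt, Ft, yt, table_t = assemble_dataset(tgt)
    return {
        "Xs": Xs, "Fs": Fs, "ys": ys, "table_s": table_s,
        "Xt": Xt, "Ft": Ft, "yt": yt, "table_t": table_t,
    }


@pytest.fixture(scope="session")
def small_balanced(small_datasets):
    d = small_datasets
    counts = np.unique(d["ys"], return_counts=True)[1]
    k = min(5, int(counts.min()) - 1)
    bal = smote_balance(d["Xs"], d["Fs"], d["ys"], k=max(k, 1), seed=3)
    y_idx = np.array([LABEL_INDEX[label] for label in bal.labels])
    return bal, y_idx
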