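import numpy as np
import pandas as pd
import pytest

import mirsig
from mirsig.io import ExpressionDataset


@pytest.fixture(scope="session")
def default_panel():
    return mirsig.build_default_panel()


@pytest.fixture(scope="session")
def default_design():
    return mirsig.build_default_design()


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort, shared across tests that only read it."""
    return mirsig.simulate_default(seed=1)


@pytest.fixture(scope="session")
def default_norm(default_sim):
    return mirsig.normalize_housekeeping(default_sim.dataset)


@pytest.fixture(scope="session")
def default_de(default_norm):
    return mirsig.de_test(default_norm, alpha=0.05)


def make_dataset(counts, probe_classes, tissue_classes, patient_ids=None,
                 annotated=None):
    """Small hand-built ExpressionDataset for unit tests."""
    counts = np.asarray(counts, dtype=np.int64)
    n_probes, n_samples = counts.shape
    probe_ids = [f"p{i}" for i in range(n_probes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if annotated is None:
        annotated = [
            (f"mir-{i}",) if c == "endogenous" else ()
            for i, c in enumerate(probe_classes)
        ]
    probe_info = pd.DataFrame(
        {"probe_class": probe_classes, "annotated_mirnas": annotated},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    if patient_ids is None:
        patient_ids = [f"pt{j}" for j in range(n_samples)]
    sample_meta = pd.DataFrame(
        {"patient_id": patient_ids, "tissue_class": tissue_classes},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(
        counts=pd.DataFrame(counts, index=probe_info.index, columns=sample_meta.index),
        probe_info=probe_info,
        sample_meta=sample_meta,
    )
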