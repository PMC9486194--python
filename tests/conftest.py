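import numpy as np
import pandas as pd
import pytest

from cmskit import synthetic as syn


@pytest.fixture(scope="session")
def balanced_cohort():
    """Well-separated 4-subtype cohort (n=300) with its true labels."""
    spec = syn.CohortSpec(
        n_samples=300,
        n_genes=300,
        subtype_proportions=(0.25, 0.25, 0.25, 0.25),
        signature_sizes=(20, 20, 20, 20),
        effect_size=3.0,
        seed=11,
    )
    cohort, labels = syn.generate_reference_cohort(spec)
    return spec, cohort, labels


@pytest.fixture(scope="session")
def cms4_markers(balanced_cohort):
    spec, _, _ = balanced_cohort
    return syn.marker_genes(spec)["CMS4"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def paired_design():
    """Patient/arm labels for a 5-patient, 3+3-biopsy paired design."""
    patients = np.repeat([f"P{i}" for i in range(5)], 6)
    arms = np.tile(["PRE"] * 3 + ["POST"] * 3, 5)
    return patients, arms
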