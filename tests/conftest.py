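import numpy as np
import pandas as pd
import pytest

from t2asym.atlas import make_atlas
from t2asym.contralateral import assemble_table
from t2asym.features import extract_all
from t2asym.phantom import PhantomSpec, simulate_cohort
from t2asym.t2map import compute_t2_map


def cohort_feature_table(spec: PhantomSpec, use_echo_labels: bool = True):
    """Simulate a cohort and build its analysis table from ground-truth labels."""
    subjects, cohort, atlas = simulate_cohort(spec)
    dfs = {}
    for s in subjects:
        tmap = compute_t2_map(s.echo_a, s.echo_b)
        labels = s.labels_echo if use_echo_labels else s.labels
        dfs[s.subject_id] = extract_all(tmap, labels, atlas)
    return assemble_table(dfs, cohort, atlas), atlas, subjects, cohort


@pytest.fixture(scope="session")
def planted_effect_table():
    """20-subject cohort with a strong planted hippocampus-analog asymmetry."""
    spec = PhantomSpec(
        n_mcis=10,
        n_mcip=10,
        noise_sd=10.0,
        effect_map={0: {"mean_shift": 20.0, "asym_shift": 30.0}},
        seed=42,
    )
    table, atlas, _, cohort = cohort_feature_table(spec)
    return table, atlas, cohort


@pytest.fixture(scope="session")
def mirror_table():
    """Zero-noise, zero-asymmetry cohort: perfectly mirrored hemispheres."""
    spec = PhantomSpec(
        n_mcis=2, n_mcip=2, noise_sd=0.0, s0_sd=0.0, effect_map={}, seed=7,
    )
    table, atlas, _, _ = cohort_feature_table(spec)
    return table, atlas


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(6, 1)
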