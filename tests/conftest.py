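"""Shared fixtures: one default panel, profiles and trained model per session."""

import numpy as np
import pandas as pd
import pytest

from panelcheck.classifier import train_pipeline
from panelcheck.preprocess import estimate_size_factors, vst_transform
from panelcheck.syndata import (
    GeneratorConfig, SampleAnnotation, make_panel, make_profiles, simulate_counts,
)


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def panel(config):
    return make_panel(config.n_genes, seed=config.seed)


@pytest.fixture(scope="session")
def profiles(panel, config):
    return make_profiles(panel, config)


@pytest.fixture(scope="session")
def training_data(panel, profiles, config):
    """Counts + labels for a balanced UIP / non-UIP training cohort."""
    rng = np.random.default_rng(2024)
    cols, labels = {}, []
    for cls, role in (("UIP", "uip_tbb"), ("non-UIP", "nonuip_tbb")):
        for i in range(config.n_train_per_class):
            sid = f"{role}_{i}"
            ann = SampleAnnotation(sample_id=sid, class_label=cls, tissue_role=role)
            cols[sid] = simulate_counts(profiles[role], ann, config, rng)
            labels.append(cls)
    counts = pd.DataFrame(cols, index=list(panel.gene_ids))
    return counts, np.asarray(labels)


@pytest.fixture(scope="session")
def model(training_data):
    counts, labels = training_data
    return train_pipeline(counts, labels, seed=0)


@pytest.fixture(scope="session")
def transformed_training(training_data, model):
    counts, labels = training_data
    sf = estimate_size_factors(counts)
    return vst_transform(counts, sf, model.dispersion), labels
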