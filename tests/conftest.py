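import numpy as np
import pandas as pd
import pytest

from prsport.io_formats import CohortData, ProxyMap, ScoreDefinition
from prsport.synthetic_data import GeneticArchitecture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_score():
    """Five-variant score with two ancestry weight columns."""
    variants = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(5)],
        "chrom": "1",
        "pos": 1000 + 100 * np.arange(5),
        "effect_allele": ["A", "C", "G", "T", "A"],
        "other_allele": ["G", "T", "A", "C", "G"],
    })
    return ScoreDefinition(
        score_name="small",
        variants=variants,
        log_weights={
            "EUR": np.log([1.2, 0.9, 1.5, 1.0, 1.1]),
            "AFR": np.log([1.1, 1.0, 1.3, 0.8, 1.2]),
        },
    )


@pytest.fixture
def small_architecture(rng):
    m = 20
    return GeneticArchitecture(
        n_variants=m,
        ancestral_freqs=rng.uniform(0.1, 0.9, m),
        true_log_or={"pop": rng.normal(0, 0.2, m)},
        prevalence=0.3,
        prs_liability_variance=0.4,
    )


@pytest.fixture
def tiny_cohort():
    """Hand-built 4-sample x 3-variant cohort with one missing dose."""
    variants = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 200, 300],
        "ref": ["G", "T", "A"],
        "alt": ["A", "C", "G"],
    })
    dosages = np.array([
        [0.0, 1.0, 2.0],
        [1.0, np.nan, 0.0],
        [2.0, 2.0, 1.0],
        [0.0, 0.0, 1.0],
    ])
    metadata = pd.DataFrame({
        "sample": ["s1", "s2", "s3", "s4"],
        "site": ["X", "X", "Y", "Y"],
        "status": ["case", "control", "case", "control"],
        "age": [65.0, 70.0, np.nan, 80.0],
        "stage": ["T4", None, "T2", None],
        "gleason": [6.0, np.nan, 9.0, np.nan],
    })
    return CohortData(sample_ids=["s1", "s2", "s3", "s4"], variants=variants,
                      dosages=dosages, metadata=metadata)


def build_proxy_map(rows):
    """rows: (source_id, proxy_id, r2, same_direction, rule, log_or)."""
    return ProxyMap(entries=pd.DataFrame(
        rows,
        columns=["source_id", "proxy_id", "r2", "same_direction", "rule",
                 "log_or"],
    ))
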