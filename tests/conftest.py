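import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mprakit import simulate

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


SMALL_CONFIG = simulate.SimulationConfig(
    n_variants=60, n_negative_controls=30, n_positive_controls=2,
    n_replicates_per_condition=8, barcodes_per_variant_mean=40.0,
    rng_seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (read-only)."""
    cfg = SMALL_CONFIG
    library, truth = simulate.generate_library(cfg)
    counts = simulate.generate_counts(library, truth, cfg)
    return cfg, library, truth, counts


@pytest.fixture(scope="session")
def small_summaries(small_study):
    from mprakit import qc
    cfg, library, truth, counts = small_study
    qcfg = qc.QCConfig(min_replicates=6)
    summaries, report = qc.run_qc(counts, qcfg)
    return summaries, report


def make_summaries(records):
    """Build an element-summary frame from (element, rep, cond, log2_ratio)."""
    df = pd.DataFrame(records, columns=["element_id", "replicate",
                                        "condition", "log2_ratio"])
    df["dna_sum"] = 1000
    df["rna_sum"] = (1000 * 2.0 ** df["log2_ratio"]).astype(int)
    df["n_barcodes_retained"] = 10
    df["dna_factor"] = 1.0
    df["rna_factor"] = 1.0
    return df
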