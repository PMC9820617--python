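import pytest

from glioma_cns5.simulate import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """A scaled-down cohort for fast unit tests; analyses that probe the
    study-scale composition build the full default config themselves."""
    defaults = dict(
        legacy_counts={
            "oligodendroglioma": 30,
            "oligoastrocytoma": 20,
            "astrocytoma": 30,
            "glioblastoma": 80,
            "unknown": 10,
        },
        n_background_genes=60,
        n_class_marker_genes=15,
        n_signature_genes=12,
        n_meth_background_genes=30,
        n_meth_marker_genes=10,
        n_multi_aliquot_cases=4,
        seed=17,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def sim_cohort(small_cfg):
    return simulate_cohort(small_cfg)


def zero_missingness(**overrides) -> SimConfig:
    return small_config(
        missingness={k: 0.0 for k in SimConfig().missingness},
        os_missing_rate=0.0,
        genomic_data_rate=1.0,
        **overrides,
    )
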