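import pytest

import escapeatlas as ea


@pytest.fixture(scope="session")
def acfg() -> ea.AnalysisConfig:
    return ea.AnalysisConfig()


@pytest.fixture(scope="session")
def bulk_small() -> ea.simulate.SimBulk:
    """Small two-organ bulk simulation shared by unit tests."""
    cfg = ea.SimConfig(
        seed=11,
        n_genes=120,
        organs=("heart", "kidney"),
        embryonic_organs=("heart",),
    )
    return ea.simulate_bulk(cfg)


@pytest.fixture(scope="session")
def bulk_pipeline(bulk_small, acfg):
    """(summary, calls, group_summary) for the small bulk simulation."""
    sim = bulk_small
    counts = ea.aggregate_gene_counts(sim.snp_counts, sim.genes, acfg.minread)
    summary = ea.summarize_allelic(
        counts, sim.meta, acfg.total_read_cutoff_bulk, acfg.min_informative_samples
    )
    calls, group_summary = ea.call_table(
        summary[summary["sex"] == "female"],
        summary[summary["sex"] == "male"],
        acfg,
    )
    return summary, calls, group_summary
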