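import pytest

from phosdisplay import phospho_scoring, selection_processing, synthetic_data


@pytest.fixture(scope="session")
def fixture_bundle():
    """A miniature simulated screen shared across test modules (seed 1)."""
    return synthetic_data.end_to_end_fixture(synthetic_data.SimConfig(seed=1))


@pytest.fixture(scope="session")
def merged_tables(fixture_bundle):
    peptides = {e.peptide_seq for e in fixture_bundle.design}
    return selection_processing.process_count_tables(
        fixture_bundle.tables, peptides
    )


@pytest.fixture(scope="session")
def scored_results(fixture_bundle, merged_tables):
    obs = phospho_scoring.build_pair_observations(
        merged_tables, fixture_bundle.design, "simbait"
    )
    return phospho_scoring.score_phosphosites(obs)
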