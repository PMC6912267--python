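"""Shared fixtures: one small synthetic study reused across test modules."""

import pytest

import piriscope as ps
from piriscope import annotate as ann


@pytest.fixture(scope="session")
def config():
    return ps.SimulationConfig(seed=11, depth=20_000)


@pytest.fixture(scope="session")
def study(config):
    """(bundle, molecules, truth) for the session's reference study."""
    return ps.generate_references(config)


@pytest.fixture(scope="session")
def meth_pair(config, study):
    """CPM-quantified untreated/treated collapsed tables."""
    bundle, molecules, _ = study
    nt, t = ps.simulate_methylation_pair(bundle, molecules, config)
    nt_table = ann.compute_cpm(ann.counts_to_table(nt, "NT"))
    t_table = ann.compute_cpm(ann.counts_to_table(t, "T"))
    return nt_table, t_table


@pytest.fixture(scope="session")
def annotations(study, meth_pair):
    bundle, _, _ = study
    nt_table, _ = meth_pair
    return ps.cascade_annotate(nt_table, bundle)


@pytest.fixture(scope="session")
def rip_design(config, study):
    """(counts, classes) for the full planted RIP sample set."""
    bundle, molecules, truth = study
    counts, classes = ps.simulate_rip_counts(
        bundle, molecules, config, truth.attrs["transcripts"]
    )
    return counts, classes
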