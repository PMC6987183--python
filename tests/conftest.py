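"""Shared fixtures: simulated studies are built once per session."""

import pytest

from snassembly import consensus_merge, make_scenario


@pytest.fixture(scope="session")
def scenario24():
    """The canonical study design: 200 kb repeat-free reference, 20 planted
    markers, 24 nuclei at covered fraction 0.4, error-free mock assemblies."""
    return make_scenario(seed=1)


@pytest.fixture(scope="session")
def contig_sets24(scenario24):
    return scenario24.contig_sets()


@pytest.fixture(scope="session")
def consensus24(contig_sets24):
    """Consensus assembly of the canonical study (computed once)."""
    assembly, log = consensus_merge(contig_sets24)
    return assembly, log


@pytest.fixture(scope="session")
def scenario_small():
    """A light study for pipeline-level tests: 60 kb, 8 nuclei, with repeats."""
    return make_scenario(seed=1, length=60_000, n_nuclei=8, n_markers=8,
                         with_repeats=True, segment_scale=8_000)
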