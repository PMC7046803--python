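"""Shared fixtures: the demo landscape (seed 17) and its on-disk form."""

from __future__ import annotations

import pytest

from mirreg.io_formats import write_ct_table
from mirreg.synthetic import (
    SimulationConfig, simulate_ct_table, simulate_regulatory_landscape, write_fixture,
)


@pytest.fixture(scope="session")
def demo_bundle():
    """The default demo landscape: seed 17, 2 x 200 kb chromosomes, 6 genes,
    7 miRNAs (about half intronic), 8 TFs, 0-6 planted sites per window."""
    return simulate_regulatory_landscape(SimulationConfig())


@pytest.fixture(scope="session")
def demo_fixture_dir(demo_bundle, tmp_path_factory):
    """The demo landscape serialized to standard formats, plus a CT table."""
    outdir = tmp_path_factory.mktemp("demo_fixture")
    paths = write_fixture(demo_bundle, outdir)
    table, truth = simulate_ct_table(demo_bundle.config.qpcr, seed=demo_bundle.config.seed)
    ct_path = outdir / "ct_table.tsv"
    write_ct_table(table, ct_path)
    paths["ct_table"] = ct_path
    return paths


@pytest.fixture(scope="session")
def demo_ct():
    table, truth = simulate_ct_table(seed=17)
    return table, truth
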