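"""Shared fixtures: one reduced synthetic bundle reused across the suite.

The reduced bundle (10 species, 24 genes) keeps unit tests fast; the
full default study conditions are exercised in the acceptance tests.
"""

import pytest

from syn4d import conservation_summary as cs
from syn4d import site_catalog as sc
from syn4d.synthetic_data import SimConfig, generate_bundle


def small_config(**overrides) -> SimConfig:
    base = dict(
        seed=11,
        n_species=10,
        n_genes=24,
        codons_min=120,
        codons_max=260,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture(scope="session")
def small_catalog(small_bundle):
    cat = sc.build_catalog(
        small_bundle.transcripts,
        small_bundle.genome,
        small_bundle.alignment,
        small_bundle.scores,
    )
    cs.annotate_exon_positions(cat, small_bundle.transcripts)
    return cat


@pytest.fixture(scope="session")
def small_frame(small_catalog):
    return small_catalog.to_frame()
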