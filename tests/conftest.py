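import numpy as np
import pytest

from namgwas import (AnnotationIndex, build_annotation, simulate_population,
                     uniform_map)


@pytest.fixture(scope="session")
def gmap():
    # two 2 Mb chromosomes at 25 cM/Mb: 50 cM each, map-dense like an arm
    return uniform_map({"1": 2_000_000, "2": 2_000_000}, cm_per_mb=25.0)


@pytest.fixture(scope="session")
def annotation_bundle(gmap):
    genes, seqs = build_annotation(gmap, n_genes=40, seed=5)
    return genes, seqs, AnnotationIndex(genes, seqs)


@pytest.fixture(scope="session")
def small_pop(gmap, annotation_bundle):
    _, seqs, _ = annotation_bundle
    return simulate_population(gmap, n_founders=26, n_sites=1000, n_families=5,
                               rils_per_family=50, anchors_per_chrom=25,
                               seed=3, sequences=seqs)


@pytest.fixture(scope="session")
def site_chrom(small_pop):
    return small_pop.panel.sites["chrom"].to_numpy()
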