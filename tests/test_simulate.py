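"""Population generator: founders, mosaics, genotypes, traits."""

import numpy as np
import pytest
from scipy import stats

from namgwas import (assign_trait_architecture, build_annotation,
                     simulate_founders, simulate_phenotypes,
                     simulate_population, simulate_ril_mosaics, uniform_map)
from namgwas.simulate import derive_genotypes


# ---- founders -------------------------------------------------------

def test_every_site_segregates(gmap):
    panel = simulate_founders(26, gmap, 500, seed=1)
    freq = panel.allele_freq()
    assert ((freq > 0) & (freq < 1)).all()
    assert panel.n_sites == 500


def test_same_seed_gives_identical_panels(gmap):
    a = simulate_founders(26, gmap, 200, seed=7)
    b = simulate_founders(26, gmap, 200, seed=7)
    assert (a.alleles == b.alleles).all()
    assert a.sites.equals(b.sites)
    c = simulate_founders(26, gmap, 200, seed=8)
    assert not (a.alleles == c.alleles).all()


def test_point_mass_spectrum_mean_frequency(gmap):
    n_sites = 2000
    panel = simulate_founders(26, gmap, n_sites, maf_spectrum=("point", 0.5),
                              seed=2)
    mean_f = panel.allele_freq().mean()
    se = 0.5 / np.sqrt(26 * n_sites)   # binomial se of the grand mean
    assert abs(mean_f - 0.5) < 3 * se + 0.01  # +slack for monomorphic rejection


def test_founder_preconditions(gmap):
    with pytest.raises(ValueError):
        simulate_founders(1, gmap, 10, seed=0)
    with pytest.raises(ValueError):
        simulate_founders(5, gmap, 0, seed=0)


# ---- mosaics --------------------------------------------------------

def test_crossover_count_matches_selfed_ril_expansion():
    # 1 Morgan chromosome -> Poisson mean 2 per RIL on the expanded map
    gmap = uniform_map({"1": 1_000_000}, cm_per_mb=100.0)
    mosaics = simulate_ril_mosaics(gmap, 1, 10_000, seed=4)
    n_xo = np.array([len(m.segments["1"]) - 1 for m in mosaics])
    se = np.sqrt(2.0 / len(n_xo))
    assert abs(n_xo.mean() - 2.0) < 3 * se


def test_zero_length_chromosome_is_a_single_segment():
    gmap = uniform_map({"1": 1_000_000}, cm_per_mb=0.0)
    mosaics = simulate_ril_mosaics(gmap, 1, 50, seed=4)
    assert all(len(m.segments["1"]) == 1 for m in mosaics)


def test_segments_tile_and_alternate(gmap):
    mosaics = simulate_ril_mosaics(gmap, 2, 100, seed=9)
    for m in mosaics:
        for chrom in gmap.chromosomes:
            segs = m.segments[chrom]
            assert segs[0][0] == 0
            assert segs[-1][1] == gmap.length_bp(chrom) + 1
            for (s0, e0, o0), (s1, e1, o1) in zip(segs, segs[1:]):
                assert e0 == s1
                assert o0 != o1


# ---- genotype derivation -------------------------------------------

def test_common_origin_chromosome_copies_common_parent(gmap):
    panel = simulate_founders(6, gmap, 300, seed=11)
    mosaics = simulate_ril_mosaics(gmap, 2, 30, seed=12)
    geno, anchors = derive_genotypes(mosaics, panel)
    sites = panel.sites
    common = panel.alleles[panel.common_index]
    for i, m in enumerate(mosaics):
        for chrom in gmap.chromosomes:
            if all(o == 0 for *_, o in m.segments[chrom]):
                idx = sites.index[sites["chrom"] == chrom].to_numpy()
                assert (geno[i, idx] == common[idx]).all()
    # anchors are a valid, sorted, evenly spread subset
    assert len(np.unique(anchors)) == len(anchors)
    assert set(anchors) <= set(range(panel.n_sites))


def test_shared_parent_allele_is_fixed_in_family(gmap):
    panel = simulate_founders(6, gmap, 300, seed=13)
    mosaics = simulate_ril_mosaics(gmap, 2, 40, seed=14)
    geno, _ = derive_genotypes(mosaics, panel)
    fam = np.array([m.family for m in mosaics])
    for family in (0, 1):
        founder = panel.alleles[panel.family_founder_index(family)]
        common = panel.alleles[panel.common_index]
        shared = founder == common
        rows = fam == family
        assert (geno[np.ix_(rows, np.flatnonzero(shared))]
                == founder[shared]).all()


def test_common_parent_minor_allele_is_boosted_to_half(gmap):
    """The Fig-5B mechanism: alleles carried by the common parent segregate
    in every family, so a rare minor allele it carries reaches ~0.5."""
    pop = simulate_population(gmap, n_founders=26, n_sites=1500, n_families=10,
                              rils_per_family=40, seed=21)
    freq = pop.panel.allele_freq()
    common = pop.panel.alleles[pop.panel.common_index]
    minor_is_alt = freq < 0.5
    used = [pop.panel.family_founder_index(f) for f in range(10)]
    fam_carriers = pop.panel.alleles[used].sum(axis=0)
    # rare panel-minor alt alleles carried by the common parent
    sel = minor_is_alt & (common == 1)
    assert sel.sum() > 20
    pop_freq = pop.genotypes[:, sel].mean(axis=0)
    # mechanism: the common parent transmits to half of every family, the
    # k carrier founders to half of theirs -> freq = 0.5 + 0.5 k / n_fam
    predicted = 0.5 + 0.5 * fam_carriers[sel] / 10
    assert np.abs(pop_freq - predicted).mean() < 0.02
    # common-parent-exclusive minor alleles land within 0.05 of one half
    excl = sel & (fam_carriers == 0)
    assert excl.sum() > 10
    assert (np.abs(pop.genotypes[:, excl].mean(axis=0) - 0.5) < 0.05).all()


# ---- trait architecture --------------------------------------------

@pytest.fixture(scope="module")
def arch_inputs(gmap):
    genes, seqs = build_annotation(gmap, 40, seed=5)
    from namgwas import AnnotationIndex
    index = AnnotationIndex(genes, seqs)
    panel = simulate_founders(26, gmap, 3000, seed=31, sequences=seqs)
    return index, panel


def test_no_coupling_gives_uncorrelated_effects(arch_inputs):
    index, panel = arch_inputs
    arch = assign_trait_architecture(index, panel, {"intergenic": 1.0}, 0.0,
                                     500, seed=41)
    rho, _ = stats.spearmanr(np.abs(arch.qtl["beta"]),
                             panel.maf()[arch.qtl["site_idx"]])
    assert abs(rho) < 3 / np.sqrt(500)


def test_coupling_sets_spearman_correlation(arch_inputs):
    index, panel = arch_inputs
    arch = assign_trait_architecture(index, panel, {"intergenic": 1.0}, 0.8,
                                     500, seed=42)
    rho, _ = stats.spearmanr(np.abs(arch.qtl["beta"]),
                             panel.maf()[arch.qtl["site_idx"]])
    assert rho == pytest.approx(-0.8, abs=0.1)


def test_intergenic_qtl_are_far_from_genes(arch_inputs):
    index, panel = arch_inputs
    arch = assign_trait_architecture(index, panel, {"intergenic": 1.0}, 0.5,
                                     50, seed=43)
    sites = panel.sites.iloc[arch.qtl["site_idx"]]
    for rec in sites.itertuples(index=False):
        assert index.nearest_gene_distance(rec.chrom, rec.pos) > 5000


def test_architecture_validation(arch_inputs):
    index, panel = arch_inputs
    with pytest.raises(ValueError, match="sum to 1"):
        assign_trait_architecture(index, panel, {"intergenic": 0.5}, 0.0, 10)
    with pytest.raises(ValueError, match="stop_gained"):
        assign_trait_architecture(index, panel, {"stop_gained": 1.0}, 0.0, 50)


# ---- phenotypes -----------------------------------------------------

def test_heritability_one_is_rejected(arch_inputs, gmap):
    index, panel = arch_inputs
    with pytest.raises(ValueError, match="h2"):
        assign_trait_architecture(index, panel, {"intergenic": 1.0}, 0.0, 5,
                                  seed=1, h2=1.0)


def test_null_trait_is_pure_noise(small_pop, annotation_bundle):
    _, _, index = annotation_bundle
    arch = assign_trait_architecture(index, small_pop.panel,
                                     {"intergenic": 1.0}, 0.0, 5, seed=51,
                                     h2=0.5, family_sd=0.0)
    arch.qtl["beta"] = 0.0
    ph = simulate_phenotypes(small_pop.genotypes, arch,
                             small_pop.family_labels, small_pop.ril_ids,
                             seed=52)
    y = ph["value"].to_numpy()
    for j in arch.qtl["site_idx"]:
        dose = small_pop.genotypes[:, j]
        if dose.std() == 0:
            continue  # allele absent from the sampled families
        r = np.corrcoef(y, dose)[0, 1]
        assert abs(r) < 4 / np.sqrt(len(y))


def test_realized_heritability_matches_request(gmap, annotation_bundle):
    _, seqs, index = annotation_bundle
    pop = simulate_population(gmap, 26, 1500, 5, 200, seed=53, sequences=seqs)
    arch = assign_trait_architecture(index, pop.panel, {"intergenic": 1.0},
                                     0.3, 10, seed=54, h2=0.7, family_sd=0.3)
    ph = simulate_phenotypes(pop.genotypes, arch, pop.family_labels,
                             pop.ril_ids, seed=55)
    y = ph["value"].to_numpy()
    g = pop.genotypes[:, arch.qtl["site_idx"]].astype(float) @ arch.qtl["beta"].to_numpy()
    # the noise is exactly orthogonal to [1, g, family dummies], so the
    # OLS residual of y on those recovers it and h2 = var(g)/(var(g)+var(e))
    D = np.column_stack([np.ones(len(y)), g]
                        + [(pop.family_labels == f).astype(float)
                           for f in np.unique(pop.family_labels)])
    eps = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    h2 = np.var(g) / (np.var(g) + np.var(eps))
    assert h2 == pytest.approx(0.7, abs=0.02 * 0.7)


def test_single_qtl_explains_requested_variance(gmap, annotation_bundle):
    _, seqs, index = annotation_bundle
    pop = simulate_population(gmap, 26, 200, 5, 200, seed=56, sequences=seqs,
                              maf_spectrum=("uniform", 0.2, 0.5))
    arch = assign_trait_architecture(index, pop.panel, {"intergenic": 1.0},
                                     0.0, 1, seed=57, h2=0.5, family_sd=0.0)
    ph = simulate_phenotypes(pop.genotypes, arch, pop.family_labels,
                             pop.ril_ids, seed=58)
    j = int(arch.qtl["site_idx"].iloc[0])
    r = np.corrcoef(ph["value"], pop.genotypes[:, j])[0, 1]
    assert r * r == pytest.approx(0.5, abs=0.05)
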