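"""Gene models, the consequence classifier, distances and GFF3/FASTA IO."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from namgwas import AnnotationIndex, GeneModel, VariantClass, build_annotation
from namgwas.annotation import (distance_histogram, read_fasta, read_gff3,
                                revcomp, write_fasta, write_gff3)


@pytest.fixture(scope="module")
def toy_index():
    """One + strand gene with two exons, hand-laid sequence.

    Layout on a 12 kb chromosome (0-based):
      gene span [1000, 1300): exon1 [1000, 1130) = 100 bp UTR5 + 30 bp CDS,
      intron [1130, 1230), exon2 [1230, 1300) = 30 bp CDS + 40 bp UTR3.
    CDS codons: ATG AAA CCC GGG TTT AGA | CGC AAA GAT GAA TTC ... TGA
    """
    cds = "ATGAAACCCGGGTTTAGA" + "CGCAAAGATGAATTCGCTATCGATGCTCTGGCAACCTGCTAA"
    assert len(cds) == 60 and str(Seq(cds).translate()).endswith("*")
    seq = list("A" * 20000)
    seq[1100:1130] = cds[:30]
    seq[1230:1260] = cds[30:]
    seq[1130:1132] = "GT"
    seq[1228:1230] = "AG"
    gene = GeneModel("G1", "c", 1000, 1300, "+", [(1000, 1130), (1230, 1300)],
                     [(1100, 1130), (1230, 1260)])
    far = GeneModel("G2", "c", 9000, 9400, "+", [(9000, 9400)], [(9000, 9300)])
    seq[9000:9003] = "ATG"
    seq[9297:9300] = "TAA"
    return AnnotationIndex([gene, far], {"c": "".join(seq)})


@pytest.mark.parametrize("pos, ref, alt, expected", [
    (1108, "C", "G", "synonymous"),        # CCC -> CCG, both Pro
    (1103, "A", "G", "missense"),          # AAA Lys -> GAA Glu
    (1100, "A", "C", "start_lost"),        # ATG -> CTG
    (1113, "T", "C", "missense"),          # TTT Phe -> TCT Ser
    (1131, "T", "C", "splice_site"),       # second base of the intron (GT)
    (1228, "A", "T", "splice_site"),       # penultimate intron base (AG)
    (1180, "A", "T", "intron"),
    (1050, "A", "T", "utr5"),
    (1280, "A", "T", "utr3"),
])
def test_classifier_on_hand_built_gene(toy_index, pos, ref, alt, expected):
    ann = toy_index.classify("c", pos, ref, alt)
    assert ann.most_severe.name == expected


def test_synonymous_vs_missense_codon_calls(toy_index):
    # codon 2 is AAA (Lys): AAA->AAG stays Lys, AAA->GAA becomes Glu
    assert toy_index.classify("c", 1105, "A", "G").most_severe.name == "synonymous"
    assert toy_index.classify("c", 1103, "A", "G").most_severe.name == "missense"


def test_stop_gained_and_stop_lost(toy_index):
    # last CDS codon TAA at [1257,1260); TAA->TCA loses the stop
    assert toy_index.classify("c", 1258, "A", "C").most_severe.name == "stop_lost"
    # AAA (codon 2) -> TAA gains a stop
    assert toy_index.classify("c", 1103, "A", "T").most_severe.name == "stop_gained"


def test_proximal_zones_and_distances(toy_index):
    # 3 kb upstream of G2 (gene at 9000): upstream_proximal, gene_proximal
    ann = toy_index.classify("c", 6000, "A", "T")
    assert ann.most_severe.name == "upstream_proximal"
    assert ann.zone == "gene_proximal"
    assert ann.distance_bp == 3000
    # >5 kb beyond the last gene (G2 ends at 9400) -> intergenic
    ann2 = toy_index.classify("c", 15000, "A", "T")
    assert ann2.zone == "intergenic"
    assert ann2.most_severe.name == "intergenic"
    assert ann2.distance_bp == 15000 - 9399
    # inside a gene: distance 0; one past the end: distance 1
    assert toy_index.nearest_gene_distance("c", 1150) == 0
    assert toy_index.nearest_gene_distance("c", 1300) == 1


def test_equidistant_site_resolves_to_lower_coordinate_gene():
    a = GeneModel("A", "c", 10, 20, "+", [(10, 20)], [])
    b = GeneModel("B", "c", 31, 41, "+", [(31, 41)], [])
    idx = AnnotationIndex([a, b], chrom_lengths={"c": 100})
    gene, d = idx.nearest_gene("c", 25)   # 6 bp from either gene
    assert d == 6
    assert gene.gene_id == "A"


def test_classifier_input_validation(toy_index):
    with pytest.raises(ValueError, match="equals ref"):
        toy_index.classify("c", 100, "A", "A")
    with pytest.raises(ValueError, match="beyond"):
        toy_index.classify("c", 50000, "A", "T")


def test_zone_partition_is_exhaustive(annotation_bundle, small_pop):
    _, _, index = annotation_bundle
    from namgwas import annotate_sites
    ann = annotate_sites(index, small_pop.panel.sites)
    genic = ann["distance_bp"] == 0
    prox = (ann["distance_bp"] > 0) & (ann["distance_bp"] <= 5000)
    inter = ann["distance_bp"] > 5000
    assert ((ann["zone"] == "genic") == genic).all()
    assert ((ann["zone"] == "gene_proximal") == prox).all()
    assert ((ann["zone"] == "intergenic") == inter).all()
    assert (genic.astype(int) + prox.astype(int) + inter.astype(int) == 1).all()


def test_severity_order_is_total():
    order = [c.name for c in sorted(VariantClass)]
    assert order == ["stop_gained", "stop_lost", "start_lost", "missense",
                     "splice_site", "synonymous", "utr5", "utr3", "intron",
                     "upstream_proximal", "downstream_proximal", "intergenic"]


# ---- generator <-> annotation io -----------------------------------

def test_gff3_round_trip(annotation_bundle, tmp_path):
    genes, seqs, _ = annotation_bundle
    gff = tmp_path / "genes.gff3"
    write_gff3(genes, str(gff))
    back = read_gff3(str(gff))
    assert len(back) == len(genes)
    for a, b in zip(sorted(genes, key=lambda g: (g.chrom, g.start)), back):
        assert (a.gene_id, a.chrom, a.start, a.end, a.strand) == \
               (b.gene_id, b.chrom, b.start, b.end, b.strand)
        assert a.exons == b.exons and a.cds == b.cds


def test_fasta_round_trip(annotation_bundle, tmp_path):
    _, seqs, _ = annotation_bundle
    path = tmp_path / "ref.fasta"
    write_fasta(seqs, str(path))
    assert read_fasta(str(path)) == seqs


def test_every_cds_translates_clean(annotation_bundle):
    genes, seqs, _ = annotation_bundle
    for g in genes:
        prot = str(Seq(g.coding_sequence(seqs[g.chrom])).translate())
        assert prot.startswith("M")
        assert prot.endswith("*")
        assert "*" not in prot[:-1]


def test_gene_proximal_genome_fraction_matches_interval_arithmetic(
        annotation_bundle, gmap):
    genes, seqs, index = annotation_bundle
    for chrom, seq in seqs.items():
        L = len(seq)
        covered = np.zeros(L, bool)
        for g in genes:
            if g.chrom == chrom:
                covered[max(0, g.start - 5000):min(L, g.end + 5000)] = True
        brute = covered.mean()
        # merged-interval arithmetic
        ivs = sorted((max(0, g.start - 5000), min(L, g.end + 5000))
                     for g in genes if g.chrom == chrom)
        total, hi = 0, -1
        for s, e in ivs:
            s = max(s, hi)
            total += max(0, e - s)
            hi = max(hi, e)
        assert abs(total / L - brute) < 0.01
        assert total / L == pytest.approx(brute, abs=1e-12)


def test_distance_histogram_conserves_counts():
    edges, counts = distance_histogram([1, 1, 1], bins_per_decade=4)
    assert counts[0] == 3 and counts.sum() == 3
    d = np.random.default_rng(0).integers(1, 100000, 500)
    edges, counts = distance_histogram(d, bins_per_decade=4)
    assert counts.sum() == 500
    assert distance_histogram([])[1].size == 0
    with pytest.raises(ValueError):
        distance_histogram([0, 5])
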