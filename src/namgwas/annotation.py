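"""Variant-consequence classification against a GFF3/FASTA annotation.

A deliberately small, self-contained SNP classifier in the style of the
Ensembl Variant Effect Predictor: every site receives a consequence
class per overlapping gene plus a single most-severe class, the distance
to the nearest gene, and a genic / gene-proximal / intergenic zone label
(gene-proximal means within 5 kb of a transcription start-stop span).

Coordinates are 0-based half-open internally; GFF3 is read and written
1-based closed. Only single-nucleotide substitutions are classified.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

PROXIMAL_BP = 5000
SPLICE_WINDOW = 2  # bases of intron adjacent to each junction

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class VariantClass(enum.Enum):
    """Consequence classes, most severe first (total order)."""

    stop_gained = 0
    stop_lost = 1
    start_lost = 2
    missense = 3
    splice_site = 4
    synonymous = 5
    utr5 = 6
    utr3 = 7
    intron = 8
    upstream_proximal = 9
    downstream_proximal = 10
    intergenic = 11

    def __lt__(self, other: "VariantClass") -> bool:
        return self.value < other.value


GENIC_CLASSES = frozenset(
    c for c in VariantClass
    if c.value <= VariantClass.intron.value
)


@dataclass
class GeneModel:
    """One gene with a single transcript.

    ``exons`` and ``cds`` are lists of 0-based half-open (start, end)
    intervals in ascending genomic order; the CDS is contained in the
    exons. ``start``/``end`` span the whole transcript.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(map(int, e)) for e in self.exons)
        self.cds = sorted(tuple(map(int, c)) for c in self.cds)
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of coding bases in translation order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return pos[::-1] if self.strand == "-" else pos

    def coding_sequence(self, chrom_seq: str) -> str:
        raw = "".join(chrom_seq[s:e] for s, e in self.cds)
        return revcomp(raw) if self.strand == "-" else raw


@dataclass
class VariantAnnotation:
    chrom: str
    pos: int
    most_severe: VariantClass
    per_gene: dict[str, VariantClass]
    nearest_gene: str | None
    distance_bp: int
    zone: str  # genic | gene_proximal | intergenic


class AnnotationIndex:
    """Interval-indexed gene set over a reference, ready for classification."""

    def __init__(self, genes: list[GeneModel], sequences: dict[str, str] | None = None,
                 chrom_lengths: dict[str, int] | None = None,
                 proximal_bp: int = PROXIMAL_BP):
        self.genes = list(genes)
        self.sequences = sequences or {}
        self.proximal_bp = int(proximal_bp)
        if chrom_lengths is None:
            chrom_lengths = {c: len(s) for c, s in self.sequences.items()}
        self.chrom_lengths = dict(chrom_lengths)
        self._trees: dict[str, IntervalTree] = {}
        self._spans: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gl in by_chrom.items():
            gl.sort(key=lambda g: (g.start, g.end))
            tree = IntervalTree()
            for g in gl:
                tree[g.start:g.end] = g
            self._trees[chrom] = tree
            starts = np.array([g.start for g in gl])
            ends = np.array([g.end for g in gl])
            self._spans[chrom] = (starts, ends, gl)

    # ---- distances -------------------------------------------------

    def nearest_gene(self, chrom: str, pos: int) -> tuple[GeneModel | None, int]:
        """(gene, distance in bp); distance 0 inside a transcript span.

        Ties between equidistant genes go to the lower-coordinate gene.
        """
        if chrom not in self._spans:
            return None, -1  # sentinel: no genes on this chromosome
        starts, ends, gl = self._spans[chrom]
        dist = np.maximum(np.maximum(starts - pos, pos - (ends - 1)), 0)
        i = int(np.argmin(dist))  # argmin takes the first (lowest start) on ties
        return gl[i], int(dist[i])

    def nearest_gene_distance(self, chrom: str, pos: int) -> int:
        return self.nearest_gene(chrom, pos)[1]

    # ---- classification --------------------------------------------

    def classify(self, chrom: str, pos: int, ref: str, alt: str) -> VariantAnnotation:
        if ref == alt:
            raise ValueError(f"alt allele equals ref at {chrom}:{pos + 1}")
        length = self.chrom_lengths.get(chrom)
        if length is not None and not 0 <= pos < length:
            raise ValueError(f"site {chrom}:{pos + 1} beyond chromosome end")
        per_gene: dict[str, VariantClass] = {}
        overlapping = sorted(
            (iv.data for iv in self._trees.get(chrom, IntervalTree())[pos]),
            key=lambda g: (g.start, g.gene_id),
        )
        for gene in overlapping:
            per_gene[gene.gene_id] = self._classify_in_gene(gene, pos, ref, alt)
        gene, dist = self.nearest_gene(chrom, pos)
        if per_gene:
            most = min(per_gene.values())
            return VariantAnnotation(chrom, pos, most, per_gene,
                                     overlapping[0].gene_id if dist == 0 else gene.gene_id,
                                     0, "genic")
        if gene is None:
            return VariantAnnotation(chrom, pos, VariantClass.intergenic, {},
                                     None, -1, "intergenic")
        if dist <= self.proximal_bp:
            before = pos < gene.start
            upstream = before if gene.strand == "+" else not before
            cls = (VariantClass.upstream_proximal if upstream
                   else VariantClass.downstream_proximal)
            return VariantAnnotation(chrom, pos, cls, {}, gene.gene_id, dist,
                                     "gene_proximal")
        return VariantAnnotation(chrom, pos, VariantClass.intergenic, {},
                                 gene.gene_id, dist, "intergenic")

    def _classify_in_gene(self, gene: GeneModel, pos: int, ref: str,
                          alt: str) -> VariantClass:
        for s, e in gene.introns:
            if s <= pos < e:
                if pos < s + SPLICE_WINDOW or pos >= e - SPLICE_WINDOW:
                    return VariantClass.splice_site
                return VariantClass.intron
        for s, e in gene.cds:
            if s <= pos < e:
                return self._coding_class(gene, pos, ref, alt)
        # exonic but non-coding: UTR side relative to the CDS
        in_exon = any(s <= pos < e for s, e in gene.exons)
        if not in_exon:
            return VariantClass.intron  # span gap outside exons/introns
        if not gene.cds:
            return VariantClass.utr5
        cds_lo = gene.cds[0][0]
        five_prime = (pos < cds_lo) == (gene.strand == "+")
        return VariantClass.utr5 if five_prime else VariantClass.utr3

    def _coding_class(self, gene: GeneModel, pos: int, ref: str,
                      alt: str) -> VariantClass:
        seq = self.sequences.get(gene.chrom)
        if seq is None:
            raise ValueError(f"no reference sequence for {gene.chrom}")
        coding_pos = gene.coding_positions()
        idx = int(np.nonzero(coding_pos == pos)[0][0])
        codon_i = idx // 3
        codon_pos = coding_pos[codon_i * 3:codon_i * 3 + 3]
        if len(codon_pos) < 3:
            return VariantClass.missense  # trailing partial codon: be conservative
        # ref/alt are forward-strand alleles; complement only when
        # assembling the codon in the coding orientation
        ref_fwd, alt_fwd = [], []
        for p in codon_pos:
            b = seq[p].upper()
            if p == pos:
                if ref.upper() != b:
                    raise ValueError(
                        f"ref allele {ref} does not match reference at "
                        f"{gene.chrom}:{pos + 1} (has {b})")
                alt_fwd.append(alt.upper())
            else:
                alt_fwd.append(b)
            ref_fwd.append(b)
        if gene.strand == "-":
            ref_codon = "".join(revcomp(b) for b in ref_fwd)
            alt_codon = "".join(revcomp(b) for b in alt_fwd)
        else:
            ref_codon, alt_codon = "".join(ref_fwd), "".join(alt_fwd)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            return VariantClass.synonymous
        if alt_aa == "*":
            return VariantClass.stop_gained
        if ref_aa == "*":
            return VariantClass.stop_lost
        if codon_i == 0 and ref_codon == "ATG":
            return VariantClass.start_lost
        return VariantClass.missense


def annotate_sites(index: AnnotationIndex, sites: pd.DataFrame) -> pd.DataFrame:
    """Classify a table of sites (columns chrom, pos, ref, alt).

    Returns one row per site: most_severe, zone, nearest_gene, distance_bp.
    """
    rows = []
    for rec in sites.itertuples(index=False):
        ann = index.classify(rec.chrom, int(rec.pos), rec.ref, rec.alt)
        rows.append((rec.chrom, int(rec.pos), ann.most_severe.name, ann.zone,
                     ann.nearest_gene, ann.distance_bp))
    return pd.DataFrame(rows, columns=["chrom", "pos", "most_severe", "zone",
                                       "nearest_gene", "distance_bp"])


def distance_histogram(distances, bins_per_decade: int = 4
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Counts of non-genic sites per logarithmic distance bin.

    Returns (bin_edges, counts); edges are 10**(k / bins_per_decade) in bp
    and the counts sum to the number of input distances.
    """
    d = np.asarray(list(distances), float)
    if d.size == 0:
        return np.array([]), np.array([], int)
    if (d <= 0).any():
        raise ValueError("distance histogram takes non-genic sites only (d > 0)")
    top = int(np.ceil(np.log10(d.max()) * bins_per_decade)) + 1
    edges = 10.0 ** (np.arange(0, top + 1) / bins_per_decade)
    edges[0] = 0.5  # first bin catches distance 1
    counts, _ = np.histogram(d, bins=edges)
    return edges, counts


# ---- GFF3 / FASTA -------------------------------------------------------

def write_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            gid, mid = g.gene_id, f"{g.gene_id}_T01"
            fh.write(_row(g.chrom, "gene", g.start, g.end, g.strand, ".",
                          f"ID={gid}"))
            fh.write(_row(g.chrom, "mRNA", g.start, g.end, g.strand, ".",
                          f"ID={mid};Parent={gid}"))
            for s, e in g.exons:
                fh.write(_row(g.chrom, "exon", s, e, g.strand, ".",
                              f"Parent={mid}"))
            cds_order = g.cds if g.strand == "+" else g.cds[::-1]
            done = 0
            for s, e in cds_order:
                phase = (3 - done % 3) % 3
                fh.write(_row(g.chrom, "CDS", s, e, g.strand, str(phase),
                              f"Parent={mid}"))
                done += e - s


def _row(chrom: str, kind: str, start: int, end: int, strand: str, phase: str,
         attrs: str) -> str:
    return f"{chrom}\tnamgwas\t{kind}\t{start + 1}\t{end}\t.\t{strand}\t{phase}\t{attrs}\n"


def read_gff3(path: str) -> list[GeneModel]:
    """Rebuild gene models from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(g, featuretype="mRNA"):
            exons += [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds += [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        genes.append(GeneModel(g.id, g.seqid, g.start - 1, g.end, g.strand,
                               sorted(exons), sorted(cds)))
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_fasta(sequences: dict[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
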