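"""Synthetic NAM-style population generator.

Emulates the design downstream analysis assumes: one common parent
crossed to many diverse founders, a few hundred fully inbred recombinant
lines (RILs) per family, dense biallelic founder genotypes with a
rare-skewed minor-allele-frequency spectrum, evenly spaced low-density
anchor markers observed on the RILs, a compact gene annotation with
valid coding sequences, and traits built from class-structured QTL with
an optional negative MAF / effect-size rank coupling, family effects and
noise.

All positions are 0-based half-open internally; the genetic map table
keeps the 1-based bp convention of map files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationIndex, GeneModel, VariantClass, revcomp
from .genmap import GeneticMap

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array([a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"])
_SENSE = np.array([c for c in _CODONS if c not in _STOPS and c != "ATG"])


# ---------------------------------------------------------------------
# founders

@dataclass
class FounderPanel:
    """Biallelic founder haplotypes: alleles is founders x sites in {0,1}."""

    sites: pd.DataFrame        # chrom, pos (0-based), ref, alt
    alleles: np.ndarray
    founder_ids: list[str]
    common_parent: str

    def __post_init__(self) -> None:
        if self.common_parent not in self.founder_ids:
            raise ValueError("common parent missing from founder ids")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def common_index(self) -> int:
        return self.founder_ids.index(self.common_parent)

    def family_founder_index(self, family: int) -> int:
        """Founder row for family ``family`` (0-based), skipping the common parent."""
        others = [i for i in range(len(self.founder_ids)) if i != self.common_index]
        return others[family]

    def allele_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1 - f)


def _draw_mafs(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind, *args = spec
    if kind == "point":
        return np.full(n, float(args[0]))
    if kind == "uniform":
        lo, hi = map(float, args)
        return rng.uniform(lo, hi, n)
    if kind == "beta":
        a, b = map(float, args)
        return 0.5 * rng.beta(a, b, n)
    raise ValueError(f"unknown MAF spectrum {spec!r}")


def simulate_founders(n_founders: int, gmap: GeneticMap, n_sites: int,
                      maf_spectrum=("beta", 0.5, 3.0),
                      seed: int = 0,
                      sequences: dict[str, str] | None = None) -> FounderPanel:
    """Draw founder haplotypes at sites placed uniformly on the map's bp range.

    Per site an allele frequency is drawn from ``maf_spectrum`` (a minor
    allele frequency in (0, 0.5]; which allele is minor is randomized)
    and founder alleles are Bernoulli draws, rejected and redrawn while
    monomorphic so every emitted site segregates. When a reference
    ``sequences`` dict is given, each site's ref allele is the reference
    base at its position (so variants are classifiable against that
    reference); otherwise ref/alt bases are random.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    rng = np.random.default_rng(seed)
    lengths = np.array([gmap.length_bp(c) for c in gmap.chromosomes], float)
    counts = np.maximum(1, np.round(n_sites * lengths / lengths.sum()).astype(int))
    while counts.sum() != n_sites:  # largest-remainder style fixup
        i = int(np.argmax(counts)) if counts.sum() > n_sites else int(np.argmin(counts))
        counts[i] += -1 if counts.sum() > n_sites else 1
    rows, cols = [], []
    for chrom, k in zip(gmap.chromosomes, counts):
        lo, hi = gmap.bp_range(chrom)
        pos = np.sort(rng.choice(np.arange(lo - 1, hi), size=k, replace=False))
        maf = _draw_mafs(maf_spectrum, k, rng)
        freq = np.where(rng.random(k) < 0.5, maf, 1 - maf)
        alle = (rng.random((n_founders, k)) < freq).astype(np.int8)
        mono = ~((alle.any(axis=0)) & (~alle.all(axis=0)))
        while mono.any():
            m = int(mono.sum())
            freq_m = _draw_mafs(maf_spectrum, m, rng)
            freq_m = np.where(rng.random(m) < 0.5, freq_m, 1 - freq_m)
            redraw = (rng.random((n_founders, m)) < freq_m).astype(np.int8)
            alle[:, mono] = redraw
            mono = ~((alle.any(axis=0)) & (~alle.all(axis=0)))
        if sequences is not None:
            seq = sequences[chrom]
            ref = np.array([list("ACGT").index(seq[p].upper()) for p in pos])
        else:
            ref = rng.integers(0, 4, k)
        alt = (ref + rng.integers(1, 4, k)) % 4
        for j in range(k):
            rows.append((chrom, int(pos[j]), _BASES[ref[j]], _BASES[alt[j]]))
        cols.append(alle)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    alleles = np.concatenate(cols, axis=1)
    ids = ["CP"] + [f"F{i:02d}" for i in range(1, n_founders)]
    return FounderPanel(sites, alleles, ids, "CP")


# ---------------------------------------------------------------------
# RIL mosaics

@dataclass
class RILMosaic:
    """Parental-origin mosaic of one fully inbred RIL.

    segments maps chromosome -> list of (start, end, origin) half-open
    intervals tiling [0, L); origin 0 is the common parent, 1 the family
    founder. Adjacent segments alternate origin.
    """

    family: int
    ril_id: str
    segments: dict[str, list[tuple[int, int, int]]]


def simulate_ril_mosaics(gmap: GeneticMap, n_families: int, rils_per_family: int,
                         seed: int = 0) -> list[RILMosaic]:
    """Single effective meiosis per RIL on a 2x-expanded map.

    Crossover counts per chromosome are Poisson with mean 2 x (length in
    Morgans) — the standard selfed-RIL map expansion — with positions
    uniform in cM mapped to bp by the genetic map; no interference, no
    residual heterozygosity.
    """
    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    mosaics = []
    for fam in range(n_families):
        for r in range(rils_per_family):
            segs: dict[str, list[tuple[int, int, int]]] = {}
            for chrom in chroms:
                L = gmap.length_bp(chrom) + 1  # extent [0, L)
                morgans = gmap.length_cm(chrom) / 100.0
                n_xo = rng.poisson(2.0 * morgans)
                _, cm_vals = gmap._by_chrom[chrom]
                cm = rng.uniform(cm_vals[0], cm_vals[-1], n_xo)
                bp = np.unique(np.round(gmap.bp_at(chrom, np.sort(cm))).astype(int) - 1)
                bp = bp[(bp > 0) & (bp < L)]
                bounds = np.concatenate([[0], bp, [L]])
                origin = int(rng.integers(2))
                chrom_segs = []
                for i in range(len(bounds) - 1):
                    chrom_segs.append((int(bounds[i]), int(bounds[i + 1]),
                                       (origin + i) % 2))
                segs[chrom] = chrom_segs
            mosaics.append(RILMosaic(fam, f"Z{fam + 1:03d}E{r + 1:04d}", segs))
    return mosaics


def derive_genotypes(mosaics: list[RILMosaic], panel: FounderPanel,
                     anchors_per_chrom: int = 20
                     ) -> tuple[np.ndarray, np.ndarray]:
    """True allele dosages of every RIL at every panel site, plus anchors.

    Each RIL's allele at a site is its segment-origin parent's allele.
    The anchor subset is ``anchors_per_chrom`` evenly spaced site indices
    per chromosome.
    """
    sites = panel.sites
    chrom_pos = {c: grp["pos"].to_numpy() for c, grp in sites.groupby("chrom", sort=False)}
    chrom_idx = {c: grp.index.to_numpy() for c, grp in sites.groupby("chrom", sort=False)}
    common = panel.alleles[panel.common_index]
    geno = np.empty((len(mosaics), panel.n_sites), dtype=np.int8)
    for i, mos in enumerate(mosaics):
        founder = panel.alleles[panel.family_founder_index(mos.family)]
        for chrom, pos in chrom_pos.items():
            segs = mos.segments[chrom]
            ends = np.array([e for _, e, _ in segs])
            origins = np.array([o for _, _, o in segs])
            k = np.searchsorted(ends, pos, side="right")
            if (k >= len(segs)).any() or (pos < segs[0][0]).any():
                raise ValueError(f"site outside mosaic segments on {chrom}")
            idx = chrom_idx[chrom]
            geno[i, idx] = np.where(origins[k] == 1, founder[idx], common[idx])
    anchor_idx = []
    for chrom, idx in chrom_idx.items():
        take = np.unique(np.linspace(0, len(idx) - 1,
                                     min(anchors_per_chrom, len(idx))).astype(int))
        anchor_idx.append(idx[take])
    return geno, np.concatenate(anchor_idx)


# ---------------------------------------------------------------------
# annotation

def _gene_structure(rng: np.random.Generator, intron_median: float,
                    n_exons_mean: float, protein_len_range, utr5_range,
                    utr3_range):
    n_exons = 1 + rng.poisson(max(0.0, n_exons_mean - 1))
    protein_len = int(rng.integers(*protein_len_range))
    cds_len = 3 * (protein_len + 2)  # start + protein + stop
    utr5 = int(rng.integers(*utr5_range))
    utr3 = int(rng.integers(*utr3_range))
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, cds_len), n_exons - 1, replace=False))
        chunks = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        introns = np.maximum(
            20, np.round(rng.lognormal(np.log(intron_median), 0.5, n_exons - 1))
        ).astype(int)
    else:
        chunks = np.array([cds_len])
        introns = np.array([], int)
    return utr5, utr3, chunks, introns


def build_annotation(gmap: GeneticMap, n_genes: int, seed: int = 0,
                     intron_median: float = 150.0, n_exons_mean: float = 4.0,
                     protein_len_range=(80, 400), utr5_range=(50, 300),
                     utr3_range=(100, 400), min_gap: int = 2000
                     ) -> tuple[list[GeneModel], dict[str, str]]:
    """Non-overlapping gene models plus a reference with valid ORFs.

    Every CDS begins with ATG, contains no internal stop, ends with a
    stop codon, and introns carry canonical GT..AG dinucleotides (in the
    coding orientation). Intron lengths are lognormal around the given
    median (default 150 bp, maize-like).
    """
    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    lengths = {c: gmap.length_bp(c) + 1 for c in chroms}
    weights = np.array([lengths[c] for c in chroms], float)
    assign = rng.choice(len(chroms), size=n_genes, p=weights / weights.sum())
    sequences = {c: "".join(rng.choice(_BASES, lengths[c])) for c in chroms}
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = int((assign == ci).sum())
        if n_here == 0:
            continue
        built = []
        for _ in range(n_here):
            utr5, utr3, chunks, introns = _gene_structure(
                rng, intron_median, n_exons_mean, protein_len_range,
                utr5_range, utr3_range)
            built.append((utr5, utr3, chunks, introns))
        gene_lens = [u5 + u3 + int(ch.sum()) + int(ii.sum())
                     for u5, u3, ch, ii in built]
        free = lengths[chrom] - sum(gene_lens) - min_gap * (n_here + 1)
        if free < 0:
            raise ValueError(f"cannot pack {n_here} genes into {chrom}")
        gaps = np.sort(rng.uniform(0, free, n_here))
        offset = 0
        for j, (u5, u3, chunks, introns) in enumerate(built):
            start = int(gaps[j]) + min_gap * (j + 1) + offset
            offset += gene_lens[j]
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _lay_out_gene(f"GENE{gi + 1:04d}", chrom, start, strand,
                                 u5, u3, chunks, introns)
            genes.append(gene)
            gi += 1
    return genes, _apply_gene_sequences(sequences, genes, rng)


def _coding_seq(n_codons_total: int, rng: np.random.Generator) -> str:
    body = rng.choice(_SENSE, n_codons_total - 2)
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + "".join(body) + stop


def _lay_out_gene(gene_id, chrom, start, strand, utr5, utr3, chunks,
                  introns) -> GeneModel:
    # build in transcript orientation, then mirror for the minus strand
    cds_len = int(chunks.sum())
    exons_rel, cds_rel = [], []
    cursor = 0
    done = 0
    n_exons = len(chunks)
    for i, ch in enumerate(chunks):
        ex_start = cursor
        if i == 0:
            cursor += utr5
        cds_rel.append((cursor, cursor + int(ch)))
        cursor += int(ch)
        done += int(ch)
        if i == n_exons - 1:
            cursor += utr3
        exons_rel.append((ex_start, cursor))
        if i < n_exons - 1:
            cursor += int(introns[i])
    gene_len = cursor
    if strand == "-":
        exons_rel = sorted((gene_len - e, gene_len - s) for s, e in exons_rel)
        cds_rel = sorted((gene_len - e, gene_len - s) for s, e in cds_rel)
    exons = [(start + s, start + e) for s, e in exons_rel]
    cds = [(start + s, start + e) for s, e in cds_rel]
    g = GeneModel(gene_id, chrom, start, start + gene_len, strand, exons, cds)
    g._cds_len = cds_len  # stashed for sequence writing
    return g


def _apply_gene_sequences(sequences: dict[str, str], genes: list[GeneModel],
                          rng: np.random.Generator) -> dict[str, str]:
    arrs = {c: np.array(list(s)) for c, s in sequences.items()}
    for g in genes:
        cds_len = getattr(g, "_cds_len", g.cds_length())
        coding = _coding_seq(cds_len // 3, rng)
        arr = arrs[g.chrom]
        # write CDS bases in transcription order
        pos = g.coding_positions()
        bases = np.array(list(coding if g.strand == "+" else revcomp(coding)))
        if g.strand == "-":
            arr[np.sort(pos)] = bases
        else:
            arr[pos] = bases
        # canonical GT..AG in coding orientation
        for s, e in g.introns:
            donor, acceptor = ("GT", "AG") if g.strand == "+" else ("CT", "AC")
            arr[s:s + 2] = list(donor)
            arr[e - 2:e] = list(acceptor)
    return {c: "".join(a) for c, a in arrs.items()}


# ---------------------------------------------------------------------
# trait architecture and phenotypes

@dataclass
class TraitArchitecture:
    """QTL plan for one trait: site indices, effects, classes, h2."""

    trait_id: str
    qtl: pd.DataFrame          # site_idx, beta, variant_class
    h2: float
    family_sd: float           # family-effect sd as a multiple of genetic sd

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        if self.family_sd < 0:
            raise ValueError("family_sd must be >= 0")


def assign_trait_architecture(index: AnnotationIndex, panel: FounderPanel,
                              class_mix: dict[str, float],
                              effect_maf_coupling: float, n_qtl: int,
                              seed: int = 0, h2: float = 0.5,
                              family_sd: float = 0.0,
                              trait_id: str = "trait",
                              beta_sigma: float = 0.7,
                              site_mask: np.ndarray | None = None,
                              spread_chromosomes: bool = False
                              ) -> TraitArchitecture:
    """Sample QTL from consequence classes with a MAF / |effect| coupling.

    ``class_mix`` maps a consequence-class or zone name (genic,
    gene_proximal, intergenic) to a proportion summing to 1. |beta| is
    lognormal, rank-coupled to founder MAF through a Gaussian copula so
    the expected Spearman correlation of |beta| with MAF equals
    ``-effect_maf_coupling``. ``site_mask`` restricts the candidate
    sites (e.g. to sites segregating in the mapping families — a QTL
    monomorphic in the population contributes nothing to the trait).
    ``spread_chromosomes`` balances QTL across chromosomes instead of
    letting them cluster by chance.
    """
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if not -1 <= effect_maf_coupling <= 1:
        raise ValueError("effect_maf_coupling must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    ann = _site_classes(index, panel)
    chosen: list[int] = []
    labels: list[str] = []
    names = list(class_mix)
    counts = _largest_remainder(np.array([class_mix[k] for k in names]), n_qtl)
    for name, k in zip(names, counts):
        if k == 0:
            continue
        mask = (ann["most_severe"] == name) | (ann["zone"] == name)
        mask = mask.to_numpy()
        if site_mask is not None:
            mask &= np.asarray(site_mask, bool)
        mask[chosen] = False
        avail = np.flatnonzero(mask)
        if len(avail) < k:
            raise ValueError(f"class {name!r} has {len(avail)} sites, need {k}")
        if spread_chromosomes:
            site_chrom = panel.sites["chrom"].to_numpy()
            quota = int(np.ceil(n_qtl / panel.sites["chrom"].nunique()))
            load = {c: int((site_chrom[chosen] == c).sum())
                    for c in panel.sites["chrom"].unique()}
            pick = []
            for j in rng.permutation(avail):
                if load[site_chrom[j]] < quota:
                    pick.append(int(j))
                    load[site_chrom[j]] += 1
                    if len(pick) == k:
                        break
            if len(pick) < k:  # quotas exhausted: fall back to free sampling
                rest = [int(j) for j in rng.permutation(avail) if j not in pick]
                pick += rest[:k - len(pick)]
            pick = np.array(pick)
        else:
            pick = rng.choice(avail, k, replace=False)
        chosen += pick.tolist()
        labels += [name] * k
    chosen = np.array(chosen)
    maf = panel.maf()[chosen]
    # Gaussian-copula inversion: Spearman rho_s corresponds to 2 sin(pi rho_s / 6)
    rho = 2 * np.sin(np.pi * float(effect_maf_coupling) / 6)
    ranks = stats.rankdata(maf + rng.normal(0, 1e-9, len(maf)))  # random tie-break
    z_m = stats.norm.ppf(ranks / (len(maf) + 1))
    z_b = -rho * z_m + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=len(maf))
    mags = np.exp(beta_sigma * z_b)
    beta = mags * rng.choice([-1.0, 1.0], len(maf))
    qtl = pd.DataFrame({"site_idx": chosen, "beta": beta, "variant_class": labels})
    return TraitArchitecture(trait_id, qtl, h2, family_sd)


def _largest_remainder(props: np.ndarray, total: int) -> np.ndarray:
    raw = props * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


_CLASS_CACHE: dict[int, pd.DataFrame] = {}


def _site_classes(index: AnnotationIndex, panel: FounderPanel) -> pd.DataFrame:
    key = (id(index), id(panel))
    if key not in _CLASS_CACHE:
        from .annotation import annotate_sites
        _CLASS_CACHE[key] = annotate_sites(index, panel.sites)
    return _CLASS_CACHE[key]


def simulate_phenotypes(genotypes: np.ndarray, architecture: TraitArchitecture,
                        family_labels: np.ndarray, ril_ids: list[str],
                        seed: int = 0) -> pd.DataFrame:
    """BLUP-like line values: family effect + sum(beta * dosage) + noise.

    The noise is drawn, made exactly orthogonal to the genetic score and
    the family dummies, and scaled so the realized heritability equals
    the architecture's h2 by construction. Heritability is defined
    conditional on family: h2 = var(genetic score) / (var(genetic
    score) + var(noise)), with the family effect excluded from both
    sides — it is the design nuisance every downstream model absorbs
    with a family covariate, and with only a handful of families its
    realized variance is too erratic to budget against.
    """
    rng = np.random.default_rng(seed)
    idx = architecture.qtl["site_idx"].to_numpy()
    if idx.size and idx.max() >= genotypes.shape[1]:
        raise ValueError("architecture references sites beyond the genotype matrix")
    beta = architecture.qtl["beta"].to_numpy()
    g = genotypes[:, idx].astype(float) @ beta if idx.size else np.zeros(len(genotypes))
    n = len(g)
    var_g = float(np.var(g))
    sd_g = np.sqrt(var_g) if var_g > 0 else 1.0
    fams = np.asarray(family_labels)
    fam_ids = np.unique(fams)
    fam_eff = rng.normal(0.0, architecture.family_sd * sd_g, len(fam_ids))
    f = fam_eff[np.searchsorted(fam_ids, fams)]
    eps = rng.normal(size=n)
    D = np.column_stack([np.ones(n), g] + [(fams == fi).astype(float) for fi in fam_ids])
    q, _ = np.linalg.qr(D)
    eps -= q @ (q.T @ eps)
    if var_g > 0:
        var_needed = var_g * (1 - architecture.h2) / architecture.h2
        eps *= np.sqrt(var_needed / np.var(eps)) if var_needed > 0 else 0.0
    y = f + g + eps
    return pd.DataFrame({"ril_id": ril_ids, "trait_id": architecture.trait_id,
                         "value": y})


# ---------------------------------------------------------------------
# convenience bundle

@dataclass
class Population:
    """Everything the downstream stages need, in memory."""

    gmap: GeneticMap
    panel: FounderPanel
    mosaics: list[RILMosaic]
    genotypes: np.ndarray       # n_ril x n_sites true dosages in {0,1}
    anchor_idx: np.ndarray
    ril_ids: list[str] = field(default_factory=list)
    family_labels: np.ndarray = None

    @property
    def site_cm(self) -> np.ndarray:
        if not hasattr(self, "_site_cm"):
            cm = np.empty(self.panel.n_sites)
            for chrom, grp in self.panel.sites.groupby("chrom", sort=False):
                cm[grp.index] = self.gmap.cm_at(chrom, grp["pos"].to_numpy() + 1)
            self._site_cm = cm
        return self._site_cm


def simulate_population(gmap: GeneticMap, n_founders: int = 26,
                        n_sites: int = 2000, n_families: int = 5,
                        rils_per_family: int = 200,
                        anchors_per_chrom: int = 20,
                        maf_spectrum=("beta", 0.5, 3.0),
                        seed: int = 0,
                        sequences: dict[str, str] | None = None) -> Population:
    """One call from map to true genotypes, with per-purpose seed streams."""
    from ._util import derive_seed

    if n_families > n_founders - 1:
        raise ValueError("need one distinct founder per family plus the common parent")
    panel = simulate_founders(n_founders, gmap, n_sites, maf_spectrum,
                              derive_seed(seed, "founders"), sequences)
    mosaics = simulate_ril_mosaics(gmap, n_families, rils_per_family,
                                   derive_seed(seed, "mosaics"))
    geno, anchor_idx = derive_genotypes(mosaics, panel, anchors_per_chrom)
    return Population(gmap, panel, mosaics, geno, anchor_idx,
                      [m.ril_id for m in mosaics],
                      np.array([m.family for m in mosaics]))
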