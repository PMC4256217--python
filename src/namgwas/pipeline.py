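"""End-to-end pipeline: simulate -> project -> joint linkage -> GWAS ->
annotate -> enrich -> effects, with a manifest of seeds and checksums.

Every stage draws its randomness from a stream derived from the master
seed and the stage name, so a single stage can be rerun or disabled
without perturbing the others, and two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import effects as eff
from . import enrichment as enr
from . import io as nio
from ._util import derive_seed
from .genmap import uniform_map
from .gwas import GwasConfig, gwas_scan, permutation_threshold, trait_variance_explained
from .joint_linkage import chromosome_residuals, fit_joint_linkage, residual_table
from .projection import project_population
from .simulate import (assign_trait_architecture, build_annotation,
                       simulate_phenotypes, simulate_population)

ALL_STAGES = ["simulate", "project", "jointlink", "gwas", "annotate",
              "enrich", "effects"]


@dataclass
class TraitSpec:
    trait_id: str = "trait1"
    n_qtl: int = 10
    h2: float = 0.5
    family_sd: float = 0.3
    effect_maf_coupling: float = 0.5
    class_mix: dict = field(default_factory=lambda: {
        "genic": 0.4, "gene_proximal": 0.3, "intergenic": 0.3})


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "pipeline_out"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    # genome / population
    chrom_lengths: dict = field(default_factory=lambda: {"1": 2_000_000,
                                                         "2": 2_000_000})
    cm_per_mb: float = 25.0          # compressed genome, map-rich like a real arm
    n_founders: int = 26
    n_sites: int = 2000
    n_families: int = 5
    rils_per_family: int = 200
    anchors_per_chrom: int = 25
    maf_spectrum: list = field(default_factory=lambda: ["beta", 0.5, 3.0])
    n_genes: int = 60
    intron_median: float = 150.0
    # models
    traits: list = field(default_factory=lambda: [dataclasses.asdict(TraitSpec())])
    jl_entry_threshold: float = 1e-4
    gwas_p_cutoff: float | None = None    # None -> permutation-derived
    gwas_iterations: int = 100
    gwas_exclude_fraction: float = 0.20
    gwas_rmip_min: float = 0.05
    perm_n: int = 200
    perm_alpha: float = 0.01
    circular_perm_n: int = 10_000
    proximal_bp: int = 5000

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)
    manifest = {"seed": cfg.seed, "stages": {}, "outputs": {},
                "config": dataclasses.asdict(cfg)}
    state: dict = {}

    def record(stage, *paths):
        for p in paths:
            manifest["outputs"][os.path.basename(p)] = _sha256(p)

    for stage in cfg.stages:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        seed = derive_seed(cfg.seed, stage)
        manifest["stages"][stage] = {"seed": seed}
        try:
            _STAGE_FNS[stage](cfg, state, out, record, seed)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _ensure_simulated(cfg, state, seed):
    if "pop" in state:
        return
    gmap = uniform_map(cfg.chrom_lengths, cfg.cm_per_mb)
    genes, seqs = build_annotation(gmap, cfg.n_genes,
                                   derive_seed(seed, "annotation"),
                                   intron_median=cfg.intron_median)
    index = ann.AnnotationIndex(genes, seqs, proximal_bp=cfg.proximal_bp)
    pop = simulate_population(
        gmap, cfg.n_founders, cfg.n_sites, cfg.n_families, cfg.rils_per_family,
        cfg.anchors_per_chrom, tuple(cfg.maf_spectrum), seed, sequences=seqs)
    state.update(gmap=gmap, pop=pop, genes=genes, seqs=seqs, index=index)
    archs, phenos = [], []
    for i, tdict in enumerate(cfg.traits):
        t = TraitSpec(**tdict)
        arch = assign_trait_architecture(
            index, pop.panel, t.class_mix, t.effect_maf_coupling, t.n_qtl,
            derive_seed(seed, "architecture", t.trait_id), t.h2, t.family_sd,
            t.trait_id)
        ph = simulate_phenotypes(pop.genotypes, arch, pop.family_labels,
                                 pop.ril_ids,
                                 derive_seed(seed, "phenotypes", t.trait_id))
        archs.append(arch)
        phenos.append(ph)
    state["architectures"] = archs
    state["phenotypes"] = pd.concat(phenos, ignore_index=True)


def _stage_simulate(cfg, state, out, record, seed):
    _ensure_simulated(cfg, state, seed)
    pop, gmap = state["pop"], state["gmap"]
    nio.write_founder_vcf(pop.panel, out("founders.vcf"))
    nio.write_map(gmap, out("genetic_map.tsv"))
    ann.write_gff3(state["genes"], out("annotation.gff3"))
    ann.write_fasta(state["seqs"], out("reference.fasta"))
    anchors = pop.panel.sites.iloc[pop.anchor_idx].copy()
    anchors.insert(0, "site_idx", pop.anchor_idx)
    anchors["pos"] = anchors["pos"] + 1
    nio.write_table(anchors, out("anchors.tsv"))
    nio.write_table(state["phenotypes"], out("phenotypes.tsv"))
    truth = pd.concat([a.qtl.assign(trait_id=a.trait_id, h2=a.h2)
                       for a in state["architectures"]], ignore_index=True)
    nio.write_table(truth, out("architecture_truth.tsv"))
    record("simulate", out("founders.vcf"), out("genetic_map.tsv"),
           out("annotation.gff3"), out("reference.fasta"), out("anchors.tsv"),
           out("phenotypes.tsv"), out("architecture_truth.tsv"))


def _stage_project(cfg, state, out, record, seed):
    _ensure_simulated(cfg, state, derive_seed(cfg.seed, "simulate"))
    pop = state["pop"]
    state["dosages"] = project_population(pop)
    nio.write_dosage_matrix(state["dosages"], pop.panel.sites, pop.ril_ids,
                            out("projected_dosages.tsv"), out("site_index.tsv"))
    record("project", out("projected_dosages.tsv"), out("site_index.tsv"))


def _stage_jointlink(cfg, state, out, record, seed):
    _ensure_simulated(cfg, state, derive_seed(cfg.seed, "simulate"))
    pop = state["pop"]
    anchors = pop.genotypes[:, pop.anchor_idx].astype(float)
    anchor_chrom = pop.panel.sites["chrom"].to_numpy()[pop.anchor_idx]
    state["residuals"] = {}
    tables = []
    for t in cfg.traits:
        tid = t["trait_id"]
        y = state["phenotypes"].query("trait_id == @tid")["value"].to_numpy()
        model = fit_joint_linkage(y, anchors, pop.family_labels,
                                  cfg.jl_entry_threshold, tid)
        resid = chromosome_residuals(model, y, anchors, anchor_chrom,
                                     pop.family_labels)
        state["residuals"][tid] = resid
        tables.append(residual_table(resid, pop.ril_ids, tid))
    nio.write_table(pd.concat(tables, ignore_index=True), out("residuals.tsv"))
    record("jointlink", out("residuals.tsv"))


def _stage_gwas(cfg, state, out, record, seed):
    if "residuals" not in state:
        _stage_jointlink(cfg, state, out, lambda *a: None,
                         derive_seed(cfg.seed, "jointlink"))
    if "dosages" not in state:
        state["dosages"] = project_population(state["pop"])
    pop = state["pop"]
    site_chrom = pop.panel.sites["chrom"].to_numpy()
    cutoff = cfg.gwas_p_cutoff
    if cutoff is None:
        first = next(iter(state["residuals"].values()))
        resid0 = next(iter(first.values()))
        cutoff = permutation_threshold(resid0, state["dosages"], cfg.perm_n,
                                       cfg.perm_alpha,
                                       derive_seed(seed, "threshold"))
    config = GwasConfig(cutoff, cfg.gwas_iterations, cfg.gwas_exclude_fraction,
                        cfg.gwas_rmip_min, seed)
    hit_frames, r2_rows = [], []
    state["all_effects"] = {}
    for t in cfg.traits:
        tid = t["trait_id"]
        hits, all_eff = gwas_scan(state["residuals"][tid], state["dosages"],
                                  site_chrom, config, tid,
                                  family_labels=pop.family_labels)
        state["all_effects"][tid] = all_eff
        hit_frames.append(hits)
        y = state["phenotypes"].query("trait_id == @tid")["value"].to_numpy()
        r2 = trait_variance_explained(y, pop.family_labels,
                                      hits["site_idx"].to_numpy(),
                                      state["dosages"])
        r2_rows.append((tid, len(hits), r2))
    state["hits"] = pd.concat(hit_frames, ignore_index=True)
    hits_out = state["hits"].copy()
    hits_out["pos"] = pop.panel.sites["pos"].to_numpy()[
        hits_out["site_idx"].to_numpy(int)] + 1
    nio.write_table(hits_out[["site_idx", "chrom", "pos", "trait_id", "rmip",
                              "mean_effect", "n_selected"]], out("hits.tsv"))
    nio.write_table(pd.DataFrame(r2_rows, columns=["trait_id", "n_hits",
                                                   "adj_r2"]),
                    out("variance_explained.tsv"))
    state["gwas_cutoff"] = cutoff
    record("gwas", out("hits.tsv"), out("variance_explained.tsv"))


def _stage_annotate(cfg, state, out, record, seed):
    _ensure_simulated(cfg, state, derive_seed(cfg.seed, "simulate"))
    pop, index = state["pop"], state["index"]
    state["annotations"] = ann.annotate_sites(index, pop.panel.sites)
    tbl = state["annotations"].copy()
    tbl["pos"] = tbl["pos"] + 1
    nio.write_table(tbl, out("site_annotations.tsv"))
    record("annotate", out("site_annotations.tsv"))


def _stage_enrich(cfg, state, out, record, seed):
    if "annotations" not in state:
        _stage_annotate(cfg, state, out, lambda *a: None, seed)
    if "hits" not in state:
        _stage_gwas(cfg, state, out, lambda *a: None,
                    derive_seed(cfg.seed, "gwas"))
    annots = state["annotations"]
    hit_idx = np.unique(state["hits"]["site_idx"].to_numpy(int))
    input_counts = annots["zone"].value_counts().to_dict()
    hit_counts = annots.iloc[hit_idx]["zone"].value_counts().to_dict()
    n_hits = len(hit_idx)
    n_input = len(annots)
    rows = []
    chrom_lengths = {c: int(l) for c, l in cfg.chrom_lengths.items()}
    hits_pos = state["pop"].panel.sites.iloc[hit_idx][["chrom", "pos"]]
    for zone, n_in in sorted(input_counts.items()):
        k = int(hit_counts.get(zone, 0))
        p0 = n_in / n_input
        p_binom = enr.binomial_class_test(k, n_hits, p0) if n_hits else np.nan
        pred = _zone_predicate(state["index"], zone)
        circ = enr.circular_permutation_test(hits_pos, pred, chrom_lengths,
                                             cfg.circular_perm_n,
                                             derive_seed(seed, "circ", zone))
        rows.append((zone, n_in, k, n_hits * p0,
                     k / (n_hits * p0) if n_hits else np.nan, p_binom,
                     circ.p_normal_two_sided, circ.p_empirical))
    table = pd.DataFrame(rows, columns=["class", "input_count", "hit_count",
                                        "expected", "ratio", "p_binomial",
                                        "p_circular", "p_circular_empirical"])
    try:
        chi = enr.overall_chisq(input_counts, hit_counts)
        table.attrs["chisq"] = (chi.statistic, chi.df, chi.pvalue)
    except ValueError:
        pass
    nio.write_table(table, out("class_enrichment.tsv"))
    state["enrichment"] = table
    record("enrich", out("class_enrichment.tsv"))


def _zone_predicate(index: ann.AnnotationIndex, zone: str):
    merged: dict[str, np.ndarray] = {}
    pad = index.proximal_bp if zone != "genic" else 0
    for chrom, (starts, ends, _) in index._spans.items():
        ivs = sorted(zip(starts - pad, ends + pad))
        flat: list[int] = []
        for s, e in ivs:
            if flat and s <= flat[-1]:
                flat[-1] = max(flat[-1], e)
            else:
                flat += [s, e]
        merged[chrom] = np.array(flat)

    def genic_pred(chrom, positions):
        flat = merged.get(chrom)
        if flat is None:
            return np.zeros(len(positions), bool)
        return np.searchsorted(flat, positions, side="right") % 2 == 1

    if zone == "genic":
        return genic_pred
    genic_only = _zone_predicate(index, "genic") if zone == "gene_proximal" else None
    if zone == "gene_proximal":
        return lambda c, p: genic_pred(c, p) & ~genic_only(c, p)
    return lambda c, p: ~genic_pred(c, p)  # intergenic: beyond 5 kb


def _stage_effects(cfg, state, out, record, seed):
    if "hits" not in state:
        _stage_gwas(cfg, state, out, lambda *a: None,
                    derive_seed(cfg.seed, "gwas"))
    if "annotations" not in state:
        _stage_annotate(cfg, state, out, lambda *a: None, seed)
    pop = state["pop"]
    hits = state["hits"]
    quantiles = eff.standardize_effects(hits, state["all_effects"])
    nio.write_table(quantiles, out("effect_quantiles.tsv"))
    zones = state["annotations"]["zone"]
    hit_idx = hits["site_idx"].to_numpy(int)
    spectra = eff.maf_by_class(state["dosages"], zones,
                               {"input": np.arange(pop.panel.n_sites),
                                "hits": np.unique(hit_idx)})
    nio.write_table(pd.concat([df.assign(subset=k) for k, df in spectra.items()],
                              ignore_index=True), out("maf_by_class.tsv"))
    rows = []
    for t in cfg.traits:
        tid = t["trait_id"]
        sub = hits[hits["trait_id"] == tid]
        if not len(sub):
            continue
        y = state["phenotypes"].query("trait_id == @tid")["value"].to_numpy()
        idx = sub["site_idx"].to_numpy(int)
        delta = eff.marginal_variance_by_class(
            y, pop.family_labels, idx, zones.iloc[idx].to_numpy(),
            state["dosages"])
        rows += [(tid, cls, d) for cls, d in delta.items()]
    nio.write_table(pd.DataFrame(rows, columns=["trait_id", "class",
                                                "delta_adj_r2"]),
                    out("variance_by_class.tsv"))
    ld = eff.ld_decay_profile(state["dosages"],
                              pop.panel.sites["pos"].to_numpy(),
                              pop.panel.sites["chrom"].to_numpy(),
                              n_pairs=5000, max_dist=1_000_000,
                              seed=derive_seed(seed, "ld"))
    nio.write_table(ld, out("ld_profile.tsv"))
    record("effects", out("effect_quantiles.tsv"), out("maf_by_class.tsv"),
           out("variance_by_class.tsv"), out("ld_profile.tsv"))


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "project": _stage_project,
    "jointlink": _stage_jointlink,
    "gwas": _stage_gwas,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
    "effects": _stage_effects,
}


# ---------------------------------------------------------------------
# printed-count reproductions

PARALOGY_COUNTS = {
    # all paralogs: 36.4% of 970 GWAS-hit genes vs 24.2% of 39,656 genes
    "all": {"k": round(0.364 * 970), "n": 970, "p0": 0.242, "N": 39656},
    # most recent genome duplication only: 30.7% vs 20.0%
    "recent": {"k": round(0.307 * 970), "n": 970, "p0": 0.200, "N": 39656},
}


def reproduce_printed_tests() -> dict:
    """Recompute the paralogy statistics from the printed counts.

    Both Fisher background constructions are reported: 'disjoint'
    contrasts hit genes against background-minus-hit genes; 'inclusive'
    keeps hit genes inside the background column.
    """
    out = {}
    for label, c in PARALOGY_COUNTS.items():
        k, n, p0, N = c["k"], c["n"], c["p0"], c["N"]
        K = round(p0 * N)
        p_binom = enr.binomial_class_test(k, n, p0)
        _, p_fisher_disjoint = enr.gene_set_test(k, n, K, N,
                                                 background_includes_hits=True)
        _, p_fisher_inclusive = enr.gene_set_test(k, n, K, N,
                                                  background_includes_hits=False)
        out[label] = {"k": k, "n": n, "p0": p0, "K": K, "N": N,
                      "p_binomial": p_binom,
                      "p_fisher_disjoint": p_fisher_disjoint,
                      "p_fisher_inclusive": p_fisher_inclusive,
                      "ratio": (k / n) / p0}
    return out
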