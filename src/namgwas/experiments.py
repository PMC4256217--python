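"""Calibration and recovery experiments on fully synthetic populations.

These are the package's self-validation studies: a type-I-error
calibration of the permutation-derived entry threshold under null
traits, and a parameter-recovery study asking whether a known multi-QTL
architecture is found by the resampled forward-regression scan. Both
build their populations from scratch with the generator defaults, so a
single integer seed reproduces every number.
"""

from __future__ import annotations

import numpy as np

from ._util import derive_seed
from .annotation import AnnotationIndex
from .forward import _scan_many
from .genmap import uniform_map
from .gwas import GwasConfig, gwas_scan, permutation_threshold, trait_variance_explained
from .joint_linkage import chromosome_residuals, fit_joint_linkage
from .projection import project_population
from .simulate import (assign_trait_architecture, build_annotation,
                       simulate_phenotypes, simulate_population)

# a maize-like karyotype: ten chromosomes of 100 cM (compressed in bp,
# genetically realistic), anchors at ~1 per cM. Mapping experiments use
# a common-variant spectrum: rare variants informative in a single
# family project onto dozens of indistinguishable dosage patterns and
# carry no localizable signal with a handful of families.
CHROM_LENGTHS = {str(c): 4_000_000 for c in range(1, 11)}
CM_PER_MB = 25.0
MAF_SPECTRUM = ("uniform", 0.2, 0.5)


def _population(n_families, rils_per_family, n_sites, anchors_per_chrom,
                seed, with_annotation=False):
    gmap = uniform_map(CHROM_LENGTHS, CM_PER_MB)
    if with_annotation:
        n_genes = int(25 * sum(CHROM_LENGTHS.values()) / 1e6)  # ~25 genes/Mb
        genes, seqs = build_annotation(gmap, n_genes,
                                       derive_seed(seed, "annotation"))
        index = AnnotationIndex(genes, seqs)
    else:
        genes = seqs = index = None
    pop = simulate_population(gmap, 26, n_sites, n_families, rils_per_family,
                              anchors_per_chrom, MAF_SPECTRUM,
                              seed=derive_seed(seed, "pop"), sequences=seqs)
    return gmap, pop, index


def null_calibration(seed: int, n_lines: int = 500, n_markers: int = 2000,
                     n_perm: int = 500, n_runs: int = 200,
                     alpha: float = 0.01) -> dict:
    """Genome-wide false-positive rate of the permutation threshold.

    The threshold is derived once by permutation on one null residual
    vector over the projected dosage matrix; ``n_runs`` fresh null
    traits are then scanned and a run counts as a false positive when
    any marker anywhere passes the threshold (exactly the event of a
    forward regression selecting at least one marker).
    """
    n_fam = 5
    _, pop, _ = _population(n_fam, n_lines // n_fam, n_markers, 100, seed)
    dosages = project_population(pop)
    rng = np.random.default_rng(derive_seed(seed, "null-traits"))
    y0 = rng.normal(size=len(dosages))
    threshold = permutation_threshold(y0, dosages, n_perm, alpha,
                                      derive_seed(seed, "perm"))
    Y = rng.normal(size=(len(dosages), n_runs))
    minp = np.nanmin(_scan_many(Y, dosages), axis=0)
    fp = int((minp < threshold).sum())
    return {"threshold": threshold, "alpha": alpha, "n_runs": n_runs,
            "false_positives": fp, "fp_rate": fp / n_runs}


def qtl_recovery(seed: int, n_families: int = 5, rils_per_family: int = 200,
                 n_sites: int = 1000, n_qtl: int = 10, h2: float = 0.5,
                 n_iterations: int = 100, window_cm: float = 1.0) -> dict:
    """End-to-end recovery of a known 10-QTL architecture.

    Simulates the population and trait, fits the joint-linkage model on
    anchors, scans chromosome-specific residuals with a permutation
    -calibrated cutoff and 100 subsampled forward regressions, then asks
    for each true QTL whether a marker within ``window_cm`` reached the
    scan. RMIP within the window is summed (capped at 1): tightly
    linked markers share inclusion mass that belongs to one signal.

    The architecture gives every QTL an equal share of the genetic
    variance — beta proportional to 1 / sd(dosage), the design under
    which a fixed h2 is spread evenly and which itself produces the
    negative MAF / effect-size coupling seen in real architectures. A
    QTL holding only a percent of the variance is unrecoverable at any
    stability threshold and would test the architecture draw, not the
    scan.
    """
    gmap, pop, index = _population(n_families, rils_per_family, n_sites, 100,
                                   seed, with_annotation=True)
    pop_maf = np.minimum(pop.genotypes.mean(axis=0),
                         1 - pop.genotypes.mean(axis=0))
    arch = assign_trait_architecture(
        index, pop.panel,
        {"genic": 0.4, "gene_proximal": 0.3, "intergenic": 0.3},
        effect_maf_coupling=0.5, n_qtl=n_qtl,
        seed=derive_seed(seed, "arch"), h2=h2, family_sd=0.3,
        site_mask=pop_maf >= 0.2, spread_chromosomes=True)
    sd = pop.genotypes[:, arch.qtl["site_idx"]].astype(float).std(axis=0)
    arch.qtl["beta"] = np.sign(arch.qtl["beta"]) / sd
    pheno = simulate_phenotypes(pop.genotypes, arch, pop.family_labels,
                                pop.ril_ids, derive_seed(seed, "pheno"))
    y = pheno["value"].to_numpy()
    anchors = pop.genotypes[:, pop.anchor_idx].astype(float)
    anchor_chrom = pop.panel.sites["chrom"].to_numpy()[pop.anchor_idx]
    model = fit_joint_linkage(y, anchors, pop.family_labels)
    residuals = chromosome_residuals(model, y, anchors, anchor_chrom,
                                     pop.family_labels)
    dosages = project_population(pop)
    threshold = permutation_threshold(next(iter(residuals.values())), dosages,
                                      500, 0.01, derive_seed(seed, "perm"))
    config = GwasConfig(p_cutoff=threshold, n_iterations=n_iterations,
                        seed=derive_seed(seed, "scan"))
    site_chrom = pop.panel.sites["chrom"].to_numpy()
    hits, _ = gwas_scan(residuals, dosages, site_chrom, config, arch.trait_id,
                        family_labels=pop.family_labels)
    cm = pop.site_cm
    per_qtl = []
    for rec in arch.qtl.itertuples(index=False):
        qcm = cm[rec.site_idx]
        qchrom = site_chrom[rec.site_idx]
        near = hits[(hits["chrom"] == qchrom)
                    & (np.abs(cm[hits["site_idx"].to_numpy(int)] - qcm)
                       <= window_cm)]
        if len(near):
            best = near.sort_values("rmip", ascending=False).iloc[0]
            per_qtl.append({
                "site_idx": int(rec.site_idx), "beta": float(rec.beta),
                "best_rmip": float(best["rmip"]),
                "window_rmip": float(min(1.0, near["rmip"].sum())),
                "recovered_effect": float(best["mean_effect"]),
                "exact_site": bool(int(best["site_idx"]) == rec.site_idx),
            })
        else:
            per_qtl.append({"site_idx": int(rec.site_idx),
                            "beta": float(rec.beta), "best_rmip": 0.0,
                            "window_rmip": 0.0,
                            "recovered_effect": np.nan, "exact_site": False})
    recovered = [q for q in per_qtl if q["window_rmip"] >= 0.95]
    effect_errors = [abs(abs(q["recovered_effect"]) - abs(q["beta"]))
                     / abs(q["beta"])
                     for q in per_qtl if q["exact_site"] and q["window_rmip"] >= 0.95]
    adj_r2 = trait_variance_explained(y, pop.family_labels,
                                      hits["site_idx"].to_numpy(int), dosages)
    return {"threshold": threshold, "n_qtl": n_qtl,
            "n_recovered": len(recovered), "per_qtl": per_qtl,
            "n_hits": len(hits), "adj_r2": adj_r2,
            "effect_rel_errors": effect_errors,
            "median_effect_rel_error": (float(np.median(effect_errors))
                                        if effect_errors else np.nan)}
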