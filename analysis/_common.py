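"""Shared configuration for the numbered analysis drivers.

One medium-sized synthetic NAM population (5 families x 200 RILs, two
2 Mb chromosomes at 25 cM/Mb, 2000 segregating sites, 60 genes) and two
traits with different architectures. Every driver reruns its stage from
this config; stage seeds derive from the master seed, so outputs are
identical across drivers and reruns.
"""

import os

from namgwas import PipelineConfig

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "pipeline")


def config() -> PipelineConfig:
    return PipelineConfig(
        seed=20240915,
        outdir=RESULTS,
        chrom_lengths={"1": 2_000_000, "2": 2_000_000},
        cm_per_mb=25.0,
        n_founders=26, n_sites=2000, n_families=5, rils_per_family=200,
        anchors_per_chrom=50, n_genes=60,
        maf_spectrum=["uniform", 0.1, 0.5],
        gwas_p_cutoff=None,       # permutation-derived
        gwas_iterations=100, perm_n=300,
        circular_perm_n=5000,
        traits=[
            {"trait_id": "metabolite_like", "n_qtl": 6, "h2": 0.6,
             "family_sd": 0.3, "effect_maf_coupling": 0.6,
             "class_mix": {"genic": 0.5, "gene_proximal": 0.3,
                           "intergenic": 0.2}},
            {"trait_id": "architecture_like", "n_qtl": 12, "h2": 0.5,
             "family_sd": 0.3, "effect_maf_coupling": 0.4,
             "class_mix": {"genic": 0.25, "gene_proximal": 0.25,
                           "intergenic": 0.5}},
        ],
    )


def run_stage(stage: str):
    cfg = config()
    cfg.stages = [stage]
    from namgwas import run_pipeline
    return cfg, run_pipeline(cfg)
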