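"""Simulate the NAM-style population, annotation and traits.

Writes founders.vcf, genetic_map.tsv, annotation.gff3, reference.fasta,
anchors.tsv, phenotypes.tsv and the QTL truth table under
results/pipeline/.
"""

import pandas as pd

from _common import RESULTS, run_stage

cfg, manifest = run_stage("simulate")
truth = pd.read_csv(f"{RESULTS}/architecture_truth.tsv", sep="\t")
pheno = pd.read_csv(f"{RESULTS}/phenotypes.tsv", sep="\t")
print(f"simulated {cfg.n_families} families x {cfg.rils_per_family} RILs, "
      f"{cfg.n_sites} sites, {cfg.n_genes} genes")
for tid, grp in truth.groupby("trait_id"):
    print(f"  trait {tid}: {len(grp)} QTL, classes "
          f"{grp['variant_class'].value_counts().to_dict()}")
print(f"phenotype table: {len(pheno)} line values "
      f"({pheno['trait_id'].nunique()} traits)")
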