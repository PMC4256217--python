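"""Effect-size standardization, MAF spectra, variance partitioning, LD.

Writes effect_quantiles.tsv (per trait-polymorphism ECDF quantile
scores), maf_by_class.tsv (folded spectra for input and hit sites),
variance_by_class.tsv (leave-class-out delta adjusted R^2) and
ld_profile.tsv (r^2 percentile curves against distance).
"""

import pandas as pd

from _common import RESULTS, run_stage

cfg, manifest = run_stage("effects")
quant = pd.read_csv(f"{RESULTS}/effect_quantiles.tsv", sep="\t")
print(f"effect quantiles: {len(quant)} trait-polymorphism combinations, "
      f"median score {quant['quantile_score'].median():.2f}")
maf = pd.read_csv(f"{RESULTS}/maf_by_class.tsv", sep="\t")
for subset, grp in maf.groupby("subset"):
    print(f"  {subset}: median MAF {grp['maf'].median():.3f} over {len(grp)} sites")
var = pd.read_csv(f"{RESULTS}/variance_by_class.tsv", sep="\t")
print(var.to_string(index=False))
ld = pd.read_csv(f"{RESULTS}/ld_profile.tsv", sep="\t")
print(f"LD: median r^2 {ld['p50'].iloc[0]:.2f} in the nearest distance bin, "
      f"{ld['p50'].iloc[-1]:.2f} in the farthest")
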