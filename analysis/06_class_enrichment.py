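"""Test the GWAS hits for consequence-class enrichment.

Hit-class counts against the input proportions: overall chi-square
(classes with expected counts below 5 dropped), per-class two-sided
exact binomial, and the circular-permutation null that rotates hit
positions with their spacing intact. Writes class_enrichment.tsv.
"""

import pandas as pd

from _common import RESULTS, run_stage

cfg, manifest = run_stage("enrich")
tab = pd.read_csv(f"{RESULTS}/class_enrichment.tsv", sep="\t")
print(tab.to_string(index=False))
enriched = tab[(tab["ratio"] > 1) & (tab["p_binomial"] < 0.05)]
if len(enriched):
    print("enriched classes:", ", ".join(enriched["class"]))
else:
    print("no class significantly enriched at the binomial 0.05 level")
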