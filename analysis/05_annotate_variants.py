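"""Classify every site against the synthetic annotation.

Writes site_annotations.tsv: most severe consequence class, zone
(genic / gene-proximal / intergenic at the 5 kb rule) and the nearest
-gene distance per site.
"""

import pandas as pd

from _common import RESULTS, run_stage

cfg, manifest = run_stage("annotate")
ann = pd.read_csv(f"{RESULTS}/site_annotations.tsv", sep="\t")
print("consequence classes:",
      ann["most_severe"].value_counts().to_dict())
print("zones:", ann["zone"].value_counts().to_dict())
nongenic = ann[ann["distance_bp"] > 0]
near = ((nongenic["distance_bp"] >= 1000)
        & (nongenic["distance_bp"] <= 5000)).mean()
print(f"non-genic sites with nearest gene 1-5 kb away: {near:.1%}")
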