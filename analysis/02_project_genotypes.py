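"""Project founder genotypes onto the RILs from the anchor markers.

Writes projected_dosages.tsv (sites x RILs) and site_index.tsv, and
reports the dosage error against the simulated truth.
"""

import numpy as np

from _common import run_stage
from namgwas.pipeline import _ensure_simulated
from namgwas._util import derive_seed
from namgwas.projection import project_population

cfg, manifest = run_stage("project")

state = {}
_ensure_simulated(cfg, state, derive_seed(cfg.seed, "simulate"))
dos = project_population(state["pop"])
mae = np.abs(dos - state["pop"].genotypes).mean()
exact = float((np.abs(dos - state["pop"].genotypes) < 1e-9).mean())
print(f"projected {dos.shape[1]} sites onto {dos.shape[0]} RILs from "
      f"{cfg.anchors_per_chrom} anchors/chromosome (~1 per cM)")
print(f"mean absolute dosage error vs truth: {mae:.4f}; "
      f"{exact:.1%} of entries exact")
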