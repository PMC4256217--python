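"""Founder-haplotype projection onto RILs from low-density anchors.

Each RIL's parental origin is observed exactly at informative anchors
(anchors where its two parents carry different alleles) and interpolated
linearly in cM between them — the expected identity-by-descent
probability for a single effective meiosis. Beyond the terminal
informative anchors the nearest anchor's origin is extended as a
constant. Founder alleles are then projected onto every dense site as
expected dosages p * allele_founder + (1 - p) * allele_common.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .simulate import FounderPanel, Population


@dataclass
class OriginTrack:
    """Piecewise-linear founder-origin probability along one RIL."""

    ril_id: str
    nodes: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (cm, p_founder)

    def p_founder(self, chrom: str, cm) -> np.ndarray:
        if chrom not in self.nodes:
            raise KeyError(f"no origin track for chromosome {chrom!r} "
                           f"(RIL {self.ril_id})")
        xs, ps = self.nodes[chrom]
        return np.interp(np.asarray(cm, float), xs, ps)


def infer_origin(anchor_calls: np.ndarray, anchor_chrom: np.ndarray,
                 anchor_cm: np.ndarray, founder_alleles: np.ndarray,
                 common_alleles: np.ndarray, ril_id: str = "") -> OriginTrack:
    """Origin track of one RIL from its anchor genotype calls.

    Anchors must be sorted by (chromosome, position). Anchors where the
    two parents share an allele are uninformative and skipped; a
    chromosome with no informative anchor raises.
    """
    nodes = {}
    informative = founder_alleles != common_alleles
    for chrom in dict.fromkeys(anchor_chrom):  # preserve order
        m = (anchor_chrom == chrom) & informative
        if not m.any():
            raise ValueError(f"no informative anchors on {chrom} for RIL {ril_id}")
        origin = (anchor_calls[m] == founder_alleles[m]).astype(float)
        nodes[str(chrom)] = (anchor_cm[m].astype(float), origin)
    return OriginTrack(ril_id, nodes)


def project_dosages(track: OriginTrack, panel: FounderPanel, family: int,
                    site_cm: np.ndarray) -> np.ndarray:
    """Expected non-reference dosage of one RIL at every panel site."""
    af = panel.alleles[panel.family_founder_index(family)].astype(float)
    ac = panel.alleles[panel.common_index].astype(float)
    out = np.empty(panel.n_sites)
    for chrom, grp in panel.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        p = track.p_founder(str(chrom), site_cm[idx])
        out[idx] = p * af[idx] + (1 - p) * ac[idx]
    return out


def project_population(pop: Population, anchor_idx: np.ndarray | None = None
                       ) -> np.ndarray:
    """Projected dosage matrix (RILs x sites) for a simulated population.

    Anchor calls are taken from the true genotypes at the anchor subset;
    at informative anchors the projected dosage is exactly 0 or 1.
    """
    if anchor_idx is None:
        anchor_idx = pop.anchor_idx
    sites = pop.panel.sites
    cm = pop.site_cm
    a_chrom = sites["chrom"].to_numpy()[anchor_idx]
    a_cm = cm[anchor_idx]
    common = pop.panel.alleles[pop.panel.common_index][anchor_idx]
    dosages = np.empty_like(pop.genotypes, dtype=float)
    for i, (ril, fam) in enumerate(zip(pop.ril_ids, pop.family_labels)):
        founder = pop.panel.alleles[pop.panel.family_founder_index(fam)][anchor_idx]
        track = infer_origin(pop.genotypes[i, anchor_idx], a_chrom, a_cm,
                             founder, common, ril)
        dosages[i] = project_dosages(track, pop.panel, fam, cm)
    return dosages
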