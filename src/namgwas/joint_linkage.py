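"""Multi-family joint-linkage model and chromosome-specific residuals.

The joint-linkage fit is forward selection over low-density anchor
markers on top of a fixed family-mean term. The GWAS response is then
the chromosome-specific residual: for each focal chromosome the model is
refit with the family term plus every selected anchor NOT on that
chromosome, so association on the focal chromosome is not absorbed by
its own linkage QTL while background QTL elsewhere are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import ForwardResult, forward_select

DEFAULT_ENTRY_P = 1e-4


def family_design(family_labels: np.ndarray) -> np.ndarray:
    """One indicator column per family (a family-mean model, no intercept)."""
    fams = np.unique(family_labels)
    return np.column_stack([(family_labels == f).astype(float) for f in fams])


@dataclass
class JLModel:
    trait_id: str
    selected: list[int]          # anchor column indices, entry order
    entry_pvalues: list[float]
    coef: np.ndarray
    family_coef: np.ndarray
    entry_threshold: float


def fit_joint_linkage(y: np.ndarray, anchors: np.ndarray,
                      family_labels: np.ndarray,
                      entry_threshold: float = DEFAULT_ENTRY_P,
                      trait_id: str = "trait") -> JLModel:
    """Forward-select anchor markers over a family-mean base model."""
    fams = np.unique(family_labels)
    if len(fams) < 2:
        raise ValueError("joint linkage needs at least 2 families")
    base = family_design(family_labels)
    if len(y) <= base.shape[1]:
        raise ValueError("fewer lines than model terms")
    res: ForwardResult = forward_select(y, anchors, entry_threshold, base=base)
    return JLModel(trait_id, res.selected, res.entry_pvalues, res.coef,
                   res.base_coef, entry_threshold)


def chromosome_residuals(model: JLModel, y: np.ndarray, anchors: np.ndarray,
                         anchor_chrom: np.ndarray, family_labels: np.ndarray
                         ) -> dict[str, np.ndarray]:
    """Residuals per focal chromosome, refitting off-chromosome terms.

    Marker effects are re-estimated jointly in each leave-one-chromosome
    -out refit rather than reusing full-model coefficients.
    """
    base = family_design(family_labels)
    out: dict[str, np.ndarray] = {}
    for chrom in dict.fromkeys(anchor_chrom):
        keep = [j for j in model.selected if anchor_chrom[j] != chrom]
        design = np.column_stack([base] + [anchors[:, j] for j in keep]) if keep else base
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        out[str(chrom)] = y - design @ beta
    return out


def residual_table(residuals: dict[str, np.ndarray], ril_ids, trait_id: str
                   ) -> pd.DataFrame:
    rows = []
    for chrom, r in residuals.items():
        for rid, v in zip(ril_ids, r):
            rows.append((rid, trait_id, chrom, float(v)))
    return pd.DataFrame(rows, columns=["ril_id", "trait_id", "chrom", "residual"])
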