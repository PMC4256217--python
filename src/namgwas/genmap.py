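"""Genetic map: monotone bp <-> cM correspondence per chromosome.

The map is the backbone of the whole pipeline: crossovers are placed in
cM and located in bp by interpolation, and origin probabilities along a
recombinant inbred line (RIL) are interpolated in cM between anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "pos_bp", "pos_cm"]


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear genetic map.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``chrom`` (str), ``pos_bp`` (int, >=1) and ``pos_cm``
        (float, >=0). Within each chromosome ``pos_cm`` must be
        nondecreasing in ``pos_bp`` and at least two points are required
        (a single point cannot define a bp<->cM correspondence).
    """

    table: pd.DataFrame
    _by_chrom: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"genetic map missing columns {missing}")
        t = t.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in t.groupby("chrom", sort=False):
            bp = grp["pos_bp"].to_numpy(float)
            cm = grp["pos_cm"].to_numpy(float)
            if len(bp) < 2:
                raise ValueError(f"degenerate map for {chrom}: need >=2 points")
            if (np.diff(bp) <= 0).any():
                raise ValueError(f"duplicate bp positions on {chrom}")
            if (np.diff(cm) < 0).any():
                raise ValueError(f"pos_cm not monotone on {chrom}")
            if (bp < 1).any() or (cm < 0).any():
                raise ValueError(f"out-of-range map coordinates on {chrom}")
            self._by_chrom[str(chrom)] = (bp, cm)
        self.table = t

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def bp_range(self, chrom: str) -> tuple[int, int]:
        bp, _ = self._by_chrom[chrom]
        return int(bp[0]), int(bp[-1])

    def length_bp(self, chrom: str) -> int:
        lo, hi = self.bp_range(chrom)
        return hi - lo

    def length_cm(self, chrom: str) -> float:
        _, cm = self._by_chrom[chrom]
        return float(cm[-1] - cm[0])

    def cm_at(self, chrom: str, pos_bp) -> np.ndarray:
        bp, cm = self._by_chrom[chrom]
        return np.interp(np.asarray(pos_bp, float), bp, cm)

    def bp_at(self, chrom: str, pos_cm) -> np.ndarray:
        """Inverse interpolation; flat cM segments map to their left edge."""
        bp, cm = self._by_chrom[chrom]
        return np.interp(np.asarray(pos_cm, float), cm, bp)


def uniform_map(chrom_lengths_bp: dict[str, int], cm_per_mb: float = 1.5,
                points_per_chrom: int = 2) -> GeneticMap:
    """Constant-recombination-rate map over the given chromosome sizes.

    The default 1.5 cM/Mb puts a 100 Mb synthetic chromosome at 1.5 Morgans,
    in the range typical of maize chromosome arms.
    """
    rows = []
    for chrom, length in chrom_lengths_bp.items():
        bps = np.linspace(1, length, max(2, points_per_chrom))
        for b in bps:
            rows.append((str(chrom), int(round(b)), (b - 1) * cm_per_mb / 1e6))
    return GeneticMap(pd.DataFrame(rows, columns=COLUMNS))
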