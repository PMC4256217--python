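"""Category and gene-set enrichment statistics.

Covers the whole testing battery around the GWAS hits: the overall
chi-square on consequence-class counts (with the <5-expected-count
filter), per-class two-sided exact binomial tests (minlike convention,
matching R's binom.test), a circular-permutation null that rotates hit
positions along each chromosome with their spacing intact, Fisher /
binomial gene-set tests, a Benjamini-Yekutieli-adjusted gene-set scan,
and generic two-sample distribution comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ChisqResult:
    statistic: float
    df: int
    pvalue: float
    tested_classes: list[str]
    dropped_classes: list[str]


def overall_chisq(input_counts: dict[str, int], hit_counts: dict[str, int],
                  min_expected: float = 5.0) -> ChisqResult:
    """Pearson chi-square of hit-class counts against input proportions.

    Classes whose expected hit count (input fraction x total hits) is
    below ``min_expected`` are removed before testing and reported in
    ``dropped_classes``; proportions are renormalized over the survivors.
    """
    classes = [c for c in input_counts if input_counts[c] > 0]
    n_input = sum(input_counts[c] for c in classes)
    n_hits = sum(hit_counts.get(c, 0) for c in classes)
    expected = {c: n_hits * input_counts[c] / n_input for c in classes}
    keep = [c for c in classes if expected[c] >= min_expected]
    dropped = [c for c in classes if c not in keep]
    if len(keep) < 2:
        raise ValueError("fewer than 2 classes survive the expected-count filter")
    obs = np.array([hit_counts.get(c, 0) for c in keep], float)
    frac = np.array([input_counts[c] for c in keep], float)
    exp = obs.sum() * frac / frac.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(keep) - 1
    return ChisqResult(stat, df, float(stats.chi2.sf(stat, df)), keep, dropped)


def binomial_class_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p, minlike convention (as in R binom.test)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly inside (0, 1)")
    return float(stats.binomtest(k, n, p0).pvalue)


@dataclass
class CircularPermutationResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_normal: float          # one-sided upper (enrichment), normal extrapolation
    p_normal_two_sided: float
    p_empirical: float       # rank p against the sampled/enumerated null
    degenerate: bool
    null_counts: np.ndarray


def circular_permutation_test(hits: pd.DataFrame, predicate,
                              chrom_lengths: dict[str, int],
                              n_perm: int = 10_000, seed: int = 0,
                              exhaustive: bool = False
                              ) -> CircularPermutationResult:
    """Rotation null for 'how many hits satisfy a positional predicate'.

    Each permutation rotates all hit positions on a chromosome by one
    shared random offset (modulo the chromosome length), keeping their
    order and spacing intact, and re-counts hits satisfying
    ``predicate(chrom, positions) -> bool array``. The p-value is
    extrapolated from a normal fit to the null counts (as done for
    permutation counts too large to enumerate), with the empirical rank
    p reported alongside. ``exhaustive`` enumerates every offset instead
    (single-chromosome layouts only).
    """
    by_chrom = {str(c): grp["pos"].to_numpy()
                for c, grp in hits.groupby("chrom", sort=False)}
    for c in by_chrom:
        L = chrom_lengths.get(c, 0)
        if L <= 0:
            raise ValueError(f"zero-length chromosome {c!r}")
    observed = sum(int(np.asarray(predicate(c, p)).sum())
                   for c, p in by_chrom.items())
    rng = np.random.default_rng(seed)
    if exhaustive:
        if len(by_chrom) != 1:
            raise ValueError("exhaustive rotation needs a single chromosome")
        (c, pos), = by_chrom.items()
        L = chrom_lengths[c]
        null = np.array([
            int(np.asarray(predicate(c, (pos + off) % L)).sum())
            for off in range(L)
        ], float)
    else:
        if n_perm < 100:
            raise ValueError("need at least 100 permutations")
        null = np.zeros(n_perm)
        for c, pos in by_chrom.items():
            L = chrom_lengths[c]
            offs = rng.integers(0, L, n_perm)
            for i, off in enumerate(offs):
                null[i] += int(np.asarray(predicate(c, (pos + off) % L)).sum())
    mean, sd = float(null.mean()), float(null.std(ddof=1 if len(null) > 1 else 0))
    degenerate = sd == 0
    if degenerate:
        z = 0.0
        p_up = p_two = 1.0 if observed == mean else 0.0
    else:
        z = (observed - mean) / sd
        p_up = float(stats.norm.sf(z))
        p_two = float(2 * stats.norm.sf(abs(z)))
    p_emp = float((1 + (null >= observed).sum()) / (1 + len(null)))
    return CircularPermutationResult(observed, mean, sd, z, p_up, p_two,
                                     p_emp, degenerate, null)


def gene_set_test(k: int, n: int, K: int, N: int,
                  background_includes_hits: bool = True
                  ) -> tuple[float, float]:
    """(binomial p, Fisher p) for k of n hit genes in a set of K of N genes.

    The binomial test uses p0 = K / N. The Fisher table contrasts hit
    genes with the rest of the background; with
    ``background_includes_hits`` (default) the background column is the
    disjoint complement (background minus hit genes).
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError("need k <= n <= N and k <= K <= N")
    if K in (0, N):
        # degenerate set: every (or no) gene is a member, nothing to test
        p_binom = 1.0 if k == (n if K == N else 0) else 0.0
    else:
        p_binom = binomial_class_test(k, n, K / N)
    if background_includes_hits:
        rest_in, rest_out = K - k, (N - n) - (K - k)
    else:
        rest_in, rest_out = K, N - K
    if min(rest_in, rest_out) < 0:
        raise ValueError("negative derived cell in Fisher table")
    table = [[k, n - k], [rest_in, rest_out]]
    p_fisher = float(stats.fisher_exact(table).pvalue)
    return p_binom, p_fisher


def gene_set_scan(sets: dict[str, set], hit_genes: set, background: set
                  ) -> pd.DataFrame:
    """Per-set Fisher + binomial tests with Benjamini-Yekutieli FDR.

    Two-sided, so both enrichment and depletion surface; the adjusted
    p-value (column ``p_adjusted``) is the BY correction of the Fisher
    p across all sets.
    """
    if not background:
        raise ValueError("empty background gene set")
    if not hit_genes <= background:
        raise ValueError("hit genes must be a subset of the background")
    n, N = len(hit_genes), len(background)
    rows = []
    for set_id, members in sets.items():
        in_bg = members & background
        k, K = len(hit_genes & in_bg), len(in_bg)
        if K == 0:
            continue
        p_b, p_f = gene_set_test(k, n, K, N)
        expected = n * K / N
        rows.append((set_id, k, expected, k / expected if expected else np.nan,
                     p_b, p_f))
    out = pd.DataFrame(rows, columns=["set_id", "observed", "expected", "ratio",
                                      "p_binomial", "p_fisher"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_fisher"], method="fdr_by")[1]
    else:
        out["p_adjusted"] = []
    return out


def compare_distributions(values_a, values_b) -> dict[str, float]:
    """Two-sided Mann-Whitney and two-sample KS tests plus medians."""
    a = np.asarray(list(values_a), float)
    b = np.asarray(list(values_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return {"p_mannwhitney": 1.0, "p_ks": 1.0, "ks_distance": 0.0,
                "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                "median_shift": 0.0}
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    ks = stats.ks_2samp(a, b)
    return {"p_mannwhitney": float(mw.pvalue), "p_ks": float(ks.pvalue),
            "ks_distance": float(ks.statistic),
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "median_shift": float(np.median(b) - np.median(a))}
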