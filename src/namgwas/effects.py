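"""Effect standardization, MAF spectra, variance partitioning, LD decay.

Effect sizes from different traits live on incomparable scales, so each
trait's effects are reduced to quantile scores against the empirical
cumulative distribution (ECDF) of all absolute effects the model
identified for that trait, before any RMIP filtering; the retained
polymorphisms then carry the mean quantile over their trait iterations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .joint_linkage import family_design


def ecdf_quantiles(all_effects: np.ndarray, query: np.ndarray) -> np.ndarray:
    """ECDF of |all_effects| evaluated at |query| (right-continuous).

    The largest observed effect scores exactly 1; a point mass sends
    every query at that value to 1. Scores depend only on ranks, so any
    strictly monotone transform of the effects leaves them unchanged.
    """
    ref = np.sort(np.abs(np.asarray(all_effects, float)))
    if ref.size == 0:
        raise ValueError("empty effect list")
    return np.searchsorted(ref, np.abs(np.asarray(query, float)),
                           side="right") / ref.size


def standardize_effects(hits: pd.DataFrame, all_effects_by_trait: dict[str, np.ndarray]
                        ) -> pd.DataFrame:
    """Per trait-polymorphism mean quantile scores for retained hits.

    ``hits`` needs columns site_idx, trait_id and pvalues-aligned
    per-iteration effects in a ``pvalues``-like list column ``effects``
    (or a scalar ``mean_effect`` as fallback). The ECDF per trait is fit
    on ``all_effects_by_trait`` — every effect the model identified for
    that trait across iterations, pre-filter.
    """
    rows = []
    for rec in hits.itertuples(index=False):
        ref = all_effects_by_trait[rec.trait_id]
        effs = getattr(rec, "effects", None)
        if effs is None or (isinstance(effs, float) and np.isnan(effs)):
            effs = [rec.mean_effect]
        q = ecdf_quantiles(ref, np.asarray(effs, float))
        rows.append((rec.site_idx, rec.trait_id, float(np.mean(effs)),
                     float(np.mean(q))))
    out = pd.DataFrame(rows, columns=["site_idx", "trait_id", "mean_effect",
                                      "quantile_score"])
    site_mean = (out.groupby("site_idx")["quantile_score"].mean()
                 .rename("site_mean_quantile"))
    return out.merge(site_mean, on="site_idx")


def folded_maf(dosages: np.ndarray) -> np.ndarray:
    """MAF per site from RIL dosages, rounded to the nearest allele."""
    f = np.round(np.asarray(dosages, float)).mean(axis=0)
    return np.minimum(f, 1 - f)


def maf_by_class(dosages: np.ndarray, classes: pd.Series,
                 subsets: dict[str, np.ndarray] | None = None,
                 bins: int = 25) -> dict[str, pd.DataFrame]:
    """Folded site-frequency spectra per consequence class.

    ``subsets`` maps a label (e.g. "input", "hits") to site indices;
    default is one spectrum over all sites. Monomorphic sites keep MAF 0
    and are flagged rather than dropped.
    """
    maf = folded_maf(dosages)
    if subsets is None:
        subsets = {"input": np.arange(len(classes))}
    edges = np.linspace(0, 0.5, bins + 1)
    out = {}
    for label, idx in subsets.items():
        cls = classes.iloc[idx] if isinstance(classes, pd.Series) else classes[idx]
        df = pd.DataFrame({"site_idx": idx, "maf": maf[idx],
                           "variant_class": np.asarray(cls),
                           "monomorphic": maf[idx] == 0})
        df["maf_bin"] = np.clip(np.digitize(df["maf"], edges) - 1, 0, bins - 1)
        out[label] = df
    return out


def marginal_variance_by_class(y: np.ndarray, family_labels: np.ndarray,
                               hit_site_idx: np.ndarray,
                               hit_classes: np.ndarray,
                               genotypes: np.ndarray,
                               adjusted: bool = True) -> dict[str, float]:
    """Delta (adjusted) R^2 from dropping each class of hits.

    delta(class) = R2(family + all hits) - R2(family + hits not in
    class); a class with no member hits scores exactly 0. Dropping every
    hit leaves the family-only model, which is valid.
    """
    hit_site_idx = np.asarray(hit_site_idx)
    hit_classes = np.asarray(hit_classes)
    full = _r2(y, family_labels, hit_site_idx, genotypes, adjusted)
    out = {}
    for cls in dict.fromkeys(hit_classes):
        keep = hit_site_idx[hit_classes != cls]
        if len(keep) == len(hit_site_idx):
            out[str(cls)] = 0.0
            continue
        out[str(cls)] = full - _r2(y, family_labels, keep, genotypes, adjusted)
    return out


def _r2(y, family_labels, site_idx, genotypes, adjusted):
    base = family_design(family_labels)
    cols = [genotypes[:, j].astype(float) for j in np.unique(site_idx)]
    design = np.column_stack([base] + cols) if cols else base
    if design.shape[1] >= len(y):
        raise ValueError("more model terms than lines")
    fit = sm.OLS(y, design, hasconst=True).fit()
    return float(fit.rsquared_adj if adjusted else fit.rsquared)


def ld_decay_profile(dosages: np.ndarray, positions: np.ndarray,
                     chroms: np.ndarray, n_pairs: int = 10_000,
                     max_dist: int = 1_000_000,
                     percentiles=(50, 70, 90, 95), seed: int = 0,
                     bins_per_decade: int = 3) -> pd.DataFrame:
    """Percentile curves of pairwise r^2 against distance.

    Random site pairs within ``max_dist`` on the same chromosome are
    sampled; r^2 is the squared Pearson correlation of the two dosage
    columns. Pairs with a zero-variance member are skipped. Returns one
    row per log-spaced distance bin with the requested percentiles.
    """
    rng = np.random.default_rng(seed)
    n_sites = dosages.shape[1]
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    sd = dosages.std(axis=0)
    dists, r2s = [], []
    draws = 0
    while len(dists) < n_pairs and draws < 50 * n_pairs:
        m = min(4 * (n_pairs - len(dists)), 4 * n_pairs)
        draws += m
        i = rng.integers(0, n_sites, m)
        j = rng.integers(0, n_sites, m)
        ok = (i != j) & (chroms[i] == chroms[j]) & (sd[i] > 0) & (sd[j] > 0)
        d = np.abs(positions[i] - positions[j])
        ok &= (d > 0) & (d <= max_dist)
        i, j, d = i[ok], j[ok], d[ok]
        a = dosages[:, i] - dosages[:, i].mean(axis=0)
        b = dosages[:, j] - dosages[:, j].mean(axis=0)
        r = (a * b).sum(axis=0) / np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
        dists += d.tolist()
        r2s += (r * r).tolist()
    dists = np.array(dists[:n_pairs])
    r2s = np.array(r2s[:n_pairs])
    top = int(np.ceil(np.log10(max(dists.max(), 10)) * bins_per_decade))
    edges = 10.0 ** (np.arange(0, top + 1) / bins_per_decade)
    edges[0] = 0.5
    which = np.digitize(dists, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = r2s[which == b]
        if sel.size == 0:
            continue
        row = {"dist_lo": edges[b], "dist_hi": edges[b + 1], "n_pairs": sel.size,
               "mean_dist": float(dists[which == b].mean())}
        for p in percentiles:
            row[f"p{p}"] = float(np.percentile(sel, p))
        rows.append(row)
    return pd.DataFrame(rows)
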