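"""Forward stepwise OLS selection — the regression engine.

At each step every candidate marker is scored by its partial t-test
p-value when added to the current model (base covariates + previously
selected markers); the smallest-p candidate enters iff its p-value is
below the entry cutoff. The implementation keeps an orthonormal basis of
the current model and residualizes candidates incrementally, which is
algebraically identical to refitting the full OLS model per candidate
but runs in O(n m) per step.

Ties in minimum p go to the lowest column index; callers order columns
by (chromosome, position). Candidates that are collinear with the
current model are skipped and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_COLLINEAR_TOL = 1e-8


@dataclass
class ForwardResult:
    selected: list[int]                 # entry order
    entry_pvalues: list[float]
    coef: np.ndarray                    # final joint-model effects, entry order
    base_coef: np.ndarray
    skipped: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)


def _orthonormal(base: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(base)
    keep = np.abs(np.diag(r)) > _COLLINEAR_TOL * max(1.0, np.abs(r).max())
    return q[:, keep]


def forward_select(y: np.ndarray, X: np.ndarray, p_cutoff: float,
                   base: np.ndarray | None = None,
                   max_steps: int | None = None) -> ForwardResult:
    """Greedy forward selection of columns of X against response y.

    ``base`` columns (default: an intercept) are always in the model.
    Returns the selected columns in entry order with their entry
    p-values and the coefficients of the final joint OLS fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if base is None:
        base = np.ones((n, 1))
    n_base = base.shape[1]
    Q = _orthonormal(base)
    yres = y - Q @ (Q.T @ y)
    Xres = X - Q @ (Q.T @ X)
    col_scale = np.linalg.norm(X, axis=0)
    col_scale[col_scale == 0] = 1.0
    selected: list[int] = []
    entry_p: list[float] = []
    skipped: set[int] = set()
    if max_steps is None:
        max_steps = n
    while len(selected) < max_steps:
        df = n - Q.shape[1] - 1
        if df < 1:
            break
        ynorm = np.linalg.norm(yres)
        if ynorm < _COLLINEAR_TOL * max(1.0, np.linalg.norm(y)):
            break  # response fully explained (or constant)
        norms = np.linalg.norm(Xres, axis=0)
        valid = norms > _COLLINEAR_TOL * col_scale
        newly_collinear = np.flatnonzero(~valid)
        skipped.update(int(j) for j in newly_collinear if j not in selected)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (yres @ Xres) / (ynorm * norms)
        r = np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)
        t2 = r * r * df / (1 - r * r)
        pvals = stats.f.sf(t2, 1, df)  # == 2 * t.sf(|t|, df), stabler at tiny p
        pvals[~valid] = np.inf
        pvals[selected] = np.inf
        j = int(np.argmin(pvals))
        if not np.isfinite(pvals[j]) or pvals[j] >= p_cutoff:
            break
        selected.append(j)
        entry_p.append(float(pvals[j]))
        q = Xres[:, j] / norms[j]
        yres = yres - q * (q @ yres)
        Xres = Xres - np.outer(q, q @ Xres)
        Q = np.column_stack([Q, q])
    coef, base_coef = _joint_fit(y, X, base, selected)
    skipped -= set(selected)
    return ForwardResult(selected, entry_p, coef, base_coef, sorted(skipped))


def _joint_fit(y, X, base, selected):
    design = np.column_stack([base] + [X[:, j] for j in selected]) if selected else base
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    nb = base.shape[1]
    return beta[nb:], beta[:nb]


def single_marker_pvalues(y: np.ndarray, X: np.ndarray,
                          base: np.ndarray | None = None) -> np.ndarray:
    """Partial t-test p-value of each marker alone (plus base covariates)."""
    res = _scan_many(np.asarray(y, float)[:, None], X, base)
    return res[:, 0]


def _scan_many(Y: np.ndarray, X: np.ndarray,
               base: np.ndarray | None = None) -> np.ndarray:
    """P-value matrix (markers x responses) of single-marker scans."""
    n = Y.shape[0]
    if base is None:
        base = np.ones((n, 1))
    Q = _orthonormal(base)
    Yres = Y - Q @ (Q.T @ Y)
    Xres = X - Q @ (Q.T @ X)
    df = n - Q.shape[1] - 1
    if df < 1:
        raise ValueError("not enough observations for a single-marker scan")
    ynorm = np.linalg.norm(Yres, axis=0)
    if (ynorm < _COLLINEAR_TOL).any():
        raise ValueError("constant response in single-marker scan")
    xnorm = np.linalg.norm(Xres, axis=0)
    ok = xnorm > _COLLINEAR_TOL * np.maximum(np.linalg.norm(X, axis=0), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xres.T @ Yres) / np.outer(xnorm, ynorm)
    r = np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)
    t2 = r * r * df / (1 - r * r)
    p = stats.f.sf(t2, 1, df)
    p[~ok, :] = np.nan
    return p
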