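"""Expression preparation: gene filtering, GC-bias correction, rank-normal scores.

The pipeline ingests TPM values (genes x samples, with per-gene GC content
and TSS coordinates), removes genes with too many zeros, regresses GC
content out of log(1+TPM) per sample with a local *quadratic* smoother
(the loess family, degree 2), and finally replaces each gene's values by
normal scores of their ranks across samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "META_COLUMNS",
    "filter_genes",
    "loess_quadratic",
    "gc_correct",
    "quantile_normalize_gene",
    "prepare_expression",
]

META_COLUMNS = ("chrom", "tss", "gc")


def filter_genes(tpm: pd.DataFrame, max_zero_frac: float = 0.05) -> pd.DataFrame:
    """Keep genes whose zero fraction is strictly below ``max_zero_frac``.

    ``tpm`` has one row per gene with metadata columns ``chrom``, ``tss``,
    ``gc`` followed by one column per sample. Genes with missing GC content
    are dropped (they cannot be bias-corrected). An empty result warns
    rather than failing.
    """
    if tpm.index.duplicated().any():
        raise ValueError("duplicate gene_ids")
    samples = [c for c in tpm.columns if c not in META_COLUMNS]
    vals = tpm[samples].to_numpy(float)
    if (vals < 0).any():
        raise ValueError("TPM values must be nonnegative")
    zero_frac = (vals == 0).mean(axis=1)
    keep = zero_frac < max_zero_frac
    if "gc" in tpm.columns:
        keep &= tpm["gc"].notna().to_numpy()
    out = tpm.loc[keep]
    if out.empty:
        warnings.warn("no genes survive filtering", stacklevel=2)
    return out


def loess_quadratic(x: np.ndarray, y: np.ndarray, span: float = 0.75,
                    xout: np.ndarray | None = None,
                    max_exact: int = 1500) -> np.ndarray:
    """Local quadratic regression (tricube weights), loess convention.

    The neighbourhood of each fit point holds q = floor(span * n) points;
    weights are tricube in distance scaled by the q-th nearest distance.
    For n <= ``max_exact`` every point is fitted exactly; above that the
    curve is fitted at ~200 quantile knots and interpolated, which changes
    fitted values only at the smoother's own noise level.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must be aligned")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: smoother is degenerate")
    q = max(int(np.floor(span * n + 1e-9)), 3)
    q = min(q, n)

    def fit_at(x0: float) -> float:
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        if h <= 0:
            w = (d == 0).astype(float)
        else:
            u = np.clip(d / h, 0.0, 1.0)
            w = (1.0 - u ** 3) ** 3
        dx = x - x0
        X = np.column_stack([np.ones(n), dx, dx * dx])
        WX = X * w[:, None]
        beta = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)[0]
        return beta[0]

    if xout is None:
        if n <= max_exact:
            return np.array([fit_at(xi) for xi in x])
        knots = np.unique(np.quantile(x, np.linspace(0, 1, 200)))
        fk = np.array([fit_at(k) for k in knots])
        return np.interp(x, knots, fk)
    return np.array([fit_at(xi) for xi in np.asarray(xout, float)])


def gc_correct(y: np.ndarray, gc: np.ndarray, span: float = 0.75) -> np.ndarray:
    """Remove the GC trend from one sample's log(1+TPM) across genes.

    Fits y ~ loess(gc) (degree 2) and returns median(y) + residuals, so
    the corrected values keep the sample's overall level. A constant GC
    vector leaves nothing to remove: y is returned unchanged with a
    warning.
    """
    y = np.asarray(y, float)
    gc = np.asarray(gc, float)
    if len(y) < 30:
        raise ValueError("gc_correct needs at least 30 genes")
    if np.ptp(gc) == 0:
        warnings.warn("constant GC content; returning values uncorrected",
                      stacklevel=2)
        return y.copy()
    fitted = loess_quadratic(gc, y, span=span)
    return np.median(y) + (y - fitted)


def quantile_normalize_gene(values: np.ndarray) -> np.ndarray:
    """Normal scores of ranks across samples for one gene.

    Plotting positions follow the rank-normal convention
    (r - 3/8)/(n + 1/4) for n <= 10 and (r - 1/2)/n otherwise; ties get
    average ranks. All-equal input maps to zeros with a warning.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(v) == 0:
        warnings.warn("constant expression; normal scores undefined, using 0",
                      stacklevel=2)
        return np.zeros(n)
    r = stats.rankdata(v, method="average")
    if n <= 10:
        p = (r - 3.0 / 8.0) / (n + 0.25)
    else:
        p = (r - 0.5) / n
    return stats.norm.ppf(p)


def prepare_expression(tpm: pd.DataFrame, max_zero_frac: float = 0.05,
                       span: float = 0.75) -> pd.DataFrame:
    """Full preparation: filter, per-sample GC correction, per-gene scores.

    Returns a DataFrame with the same metadata columns and normal-score
    expression values; row order follows the filtered input.
    """
    kept = filter_genes(tpm, max_zero_frac=max_zero_frac)
    samples = [c for c in kept.columns if c not in META_COLUMNS]
    logv = np.log1p(kept[samples].to_numpy(float))
    gc = kept["gc"].to_numpy(float)
    corrected = np.empty_like(logv)
    for j in range(logv.shape[1]):
        corrected[:, j] = gc_correct(logv[:, j], gc, span=span)
    scores = np.apply_along_axis(quantile_normalize_gene, 1, corrected)
    meta = kept[[c for c in META_COLUMNS if c in kept.columns]]
    vals = pd.DataFrame(scores, index=kept.index, columns=samples)
    return pd.concat([meta, vals], axis=1)
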