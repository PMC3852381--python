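"""Count normalization and negative-binomial differential expression.

The test compares two groups of RNA-seq samples (population replicates,
or parental alleles within hybrids) gene by gene under a negative
binomial model with variance mu + alpha*mu^2.  Per-gene dispersions are
estimated by method of moments on normalized counts and shrunk toward a
fitted mean-dispersion trend; significance comes from a likelihood-ratio
test of a common mean against per-group means (chi-square, 1 df), with
Benjamini-Hochberg correction across genes.

Normalization follows the two-stage scheme used for between-population
comparisons: upper-quartile scaling between lanes, an optional loess GC
correction within lanes, and median-of-ratios size factors feeding the
test itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "upper_quartile_factors",
    "gc_correct",
    "size_factors_median_ratio",
    "estimate_dispersions",
    "nb_test",
    "bh_adjust",
]

#: numerical floor for dispersions (effectively Poisson below this)
MIN_DISPERSION = 1e-8


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus sample and gene annotation.

    ``counts`` is a genes-as-rows DataFrame; ``sample_meta`` (optional)
    is indexed by sample with at least a ``group`` column; ``gene_gc``
    (optional, required for GC correction) maps gene to GC proportion.
    """

    counts: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = None
    gene_gc: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if self.sample_meta is not None:
            missing = set(self.counts.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.gene_gc is not None:
            gc = self.gene_gc.reindex(self.counts.index)
            if gc.isna().any():
                raise ValueError("gene_gc missing for some genes")
            if ((gc < 0) | (gc > 1)).any():
                raise ValueError("GC proportions must lie in [0, 1]")
            self.gene_gc = gc

    def groups(self) -> pd.Series:
        if self.sample_meta is None or "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta with a 'group' column is required")
        return self.sample_meta.loc[self.counts.columns, "group"]


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def upper_quartile_factors(counts) -> pd.Series:
    """Upper-quartile scaling factors, geometric mean 1 across samples.

    The factor of a sample is proportional to the 75th percentile of
    its nonzero counts, so dividing each column by its factor equalizes
    upper quartiles between lanes.
    """
    mat = _as_frame(counts)
    q = {}
    for sample in mat.columns:
        col = mat[sample].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts")
        q[sample] = np.percentile(nz, 75)
    quartiles = pd.Series(q, dtype=float)
    return quartiles / stats.gmean(quartiles)


def gc_correct(counts, gene_gc: Optional[pd.Series] = None, span: float = 0.3) -> pd.DataFrame:
    """Remove a smooth GC trend from each sample's counts.

    Within each sample a locally-weighted regression of log(count+0.5)
    on GC content is fitted (lowess, default span 0.3) and subtracted,
    then the column total is restored.  Degenerate inputs (a single
    gene, or constant GC) are returned unchanged with a warning.
    """
    if isinstance(counts, CountMatrix):
        if gene_gc is None:
            gene_gc = counts.gene_gc
        mat = counts.counts
    else:
        mat = counts
    if gene_gc is None:
        raise ValueError("GC correction requires per-gene GC content")
    gc = gene_gc.reindex(mat.index).to_numpy(dtype=float)
    if np.isnan(gc).any():
        raise ValueError("gene_gc missing for some genes")
    if mat.shape[0] < 2 or np.ptp(gc) == 0:
        warnings.warn("GC content is constant (or a single gene): returning counts unchanged")
        return mat.copy()
    out = {}
    for sample in mat.columns:
        col = mat[sample].to_numpy(dtype=float)
        logc = np.log(col + 0.5)
        fit = lowess(logc, gc, frac=span, return_sorted=False)
        corrected = np.exp(logc - fit + fit.mean()) - 0.5
        corrected = np.clip(corrected, 0.0, None)
        total = col.sum()
        if corrected.sum() > 0 and total > 0:
            corrected *= total / corrected.sum()
        out[sample] = corrected
    return pd.DataFrame(out, index=mat.index)


def size_factors_median_ratio(counts) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over genes (restricted to
    genes with a strictly positive geometric mean across samples) of
    the ratio of that gene's count to its across-sample geometric mean.
    """
    mat = _as_frame(counts).to_numpy(dtype=float)
    frame = _as_frame(counts)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = np.log(mat[usable]) - log_geo[usable, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=frame.columns)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


# ---------------------------------------------------------------------------
# negative binomial machinery
# ---------------------------------------------------------------------------


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series,
    trend_blend: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersions, shrunk toward a mean-dispersion trend.

    Gene-wise estimates use pooled within-group method of moments on
    normalized counts: var = mean/s + alpha*mean^2 solved for alpha.
    A parametric trend alpha(mu) = a0 + a1/mu is then fitted across
    genes and blended with the gene-wise value (weight ``trend_blend``
    on the trend).
    """
    if not 0.0 <= trend_blend <= 1.0:
        raise ValueError("trend_blend must lie in [0, 1]")
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    z = counts.to_numpy(dtype=float) / s
    labels = groups.loc[counts.columns].to_numpy()
    uniq = pd.unique(labels)
    n = z.shape[1]
    resid_ss = np.zeros(z.shape[0])
    for g in uniq:
        sel = labels == g
        m = z[:, sel].mean(axis=1, keepdims=True)
        resid_ss += ((z[:, sel] - m) ** 2).sum(axis=1)
    df = max(n - len(uniq), 1)
    var = resid_ss / df
    mu = z.mean(axis=1)
    shot = mu * np.mean(1.0 / s)  # Poisson component on the normalized scale
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (var - shot) / mu**2, 0.0)
    raw = np.clip(raw, 0.0, None)

    ok = mu > 0
    if ok.sum() >= 3 and np.ptp(mu[ok]) > 0:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
    else:
        a0, a1 = float(raw[ok].mean()) if ok.any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), a0)
    alpha = trend_blend * trend + (1.0 - trend_blend) * raw
    return pd.Series(np.clip(alpha, MIN_DISPERSION, None), index=counts.index)


def _fit_nb_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorized MLE of the normalized mean q, genes in rows.

    Model: y_gj ~ NB(mean = q_g * s_j, dispersion alpha_g).  Newton
    iterations on log q; the score in log q is
    sum_j r (y - mu) / (r + mu) with r = 1/alpha.
    """
    tot = y.sum(axis=1)
    q = np.maximum(tot / s.sum(), 1e-12)
    r = 1.0 / alpha
    t = np.log(q)
    for _ in range(50):
        mu = np.exp(t)[:, None] * s
        score = (r[:, None] * (y - mu) / (r[:, None] + mu)).sum(axis=1)
        info = (r[:, None] * mu * (r[:, None] + y) / (r[:, None] + mu) ** 2).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5.0, 5.0)
        t = t + step
        if np.max(np.abs(step)) < 1e-10:
            break
    q = np.exp(t)
    q[tot == 0] = 0.0  # all-zero rows: MLE at the boundary
    return q


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log likelihood; mu = 0 cells contribute 0 iff y = 0."""
    r = 1.0 / alpha[:, None]
    safe_mu = np.maximum(mu, 1e-300)
    ll = stats.nbinom.logpmf(y, r, r / (r + safe_mu))
    ll = np.where(mu <= 0, np.where(y == 0, 0.0, -np.inf), ll)
    return ll.sum(axis=1)


def nb_test(
    counts,
    group_a: Sequence[str],
    group_b: Sequence[str],
    size_factors: Optional[pd.Series] = None,
    trend_blend: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test per gene.

    Returns a DataFrame indexed by gene with columns ``baseMean``,
    ``log2FoldChange`` (oriented group_a / group_b), ``pvalue``,
    ``padj`` and ``flag`` (empty, ``all_zero`` or ``zero_group``).
    Genes with zero counts in both groups get p = 1 and log2fc = 0.
    For a gene whose counts are zero throughout one group only, the
    reported fold change uses a 0.5 pseudo-count on both normalized
    group means (the test itself uses the raw counts).
    """
    mat = _as_frame(counts)
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValueError("each group needs at least one sample")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    missing = (set(group_a) | set(group_b)) - set(mat.columns)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    samples = group_a + group_b
    sub = mat[samples]
    if size_factors is None:
        size_factors = size_factors_median_ratio(sub)
    s = size_factors.loc[samples].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    labels = pd.Series(
        ["a"] * len(group_a) + ["b"] * len(group_b), index=samples, name="group"
    )
    alpha = estimate_dispersions(sub, size_factors, labels, trend_blend).to_numpy()

    y = sub.to_numpy(dtype=float)
    na = len(group_a)
    ya, yb = y[:, :na], y[:, na:]
    sa, sb = s[:na], s[na:]

    q_null = _fit_nb_mean(y, s, alpha)
    q_a = _fit_nb_mean(ya, sa, alpha)
    q_b = _fit_nb_mean(yb, sb, alpha)

    mu_null = q_null[:, None] * s
    mu_alt = np.concatenate([q_a[:, None] * sa, q_b[:, None] * sb], axis=1)
    lrt = 2.0 * (_nb_loglik(y, mu_alt, alpha) - _nb_loglik(y, mu_null, alpha))
    lrt = np.clip(lrt, 0.0, None)
    pvalue = stats.chi2.sf(lrt, df=1)

    mean_a = ya.sum(axis=1) / sa.sum()
    mean_b = yb.sum(axis=1) / sb.sum()
    base_mean = y.sum(axis=1) / s.sum()

    all_zero = (ya.sum(axis=1) == 0) & (yb.sum(axis=1) == 0)
    zero_group = ((mean_a == 0) | (mean_b == 0)) & ~all_zero
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(
            zero_group,
            np.log2((mean_a + 0.5) / (mean_b + 0.5)),
            np.log2(mean_a / mean_b),
        )
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalue = np.where(all_zero, 1.0, pvalue)

    flag = np.where(all_zero, "all_zero", np.where(zero_group, "zero_group", ""))
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "flag": flag,
        },
        index=mat.index.rename("gene"),
    )
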