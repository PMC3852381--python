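"""Relative qPCR quantification by the 2^-ddCt method.

Cycle thresholds are first averaged over technical replicates; each
gene's Ct is normalized to the reference gene (ACT1 equivalent) within
the same genotype x biological replicate (dCt), then to the calibrator
genotype's mean dCt (ddCt); relative expression is 2^-ddCt.  For
cross-experiment comparability, log2 expression vectors can be centered
on their median within a strain background / replicate set.  Regulon-
level differences between genotypes are assessed with a two-sided
paired Wilcoxon signed-rank test over the regulon's genes.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from divergene.regulon import GeneSet

__all__ = ["ddct", "median_center", "median_center_table", "regulon_wilcoxon"]

REQUIRED_COLUMNS = ("genotype", "gene", "replicate", "ct")


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_genotype: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression from a long-format Ct table.

    ``table`` needs columns genotype, gene, replicate (biological) and
    ct; an optional ``tech_rep`` column is collapsed by mean Ct first.
    Returns one row per genotype x gene x replicate with columns
    ``value`` (2^-ddCt, calibrator-mean = 1 by construction) and
    ``log2_value``.  Replicates lacking the reference gene are dropped
    with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ct = (
        table.groupby(["genotype", "gene", "replicate"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(["genotype", "replicate"])["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    targets = ct[ct["gene"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(targets[["genotype", "replicate"]])
    ref_ct = ref.reindex(key).to_numpy()
    dropped = np.isnan(ref_ct)
    if dropped.any():
        bad = targets.loc[dropped, ["genotype", "replicate"]].drop_duplicates()
        warnings.warn(
            "dropping replicates without a reference-gene Ct: "
            + ", ".join(f"{g}/{r}" for g, r in bad.itertuples(index=False))
        )
        targets = targets.loc[~dropped].copy()
        ref_ct = ref_ct[~dropped]
    targets["dct"] = targets["ct"].to_numpy() - ref_ct
    cal = targets[targets["genotype"] == calibrator_genotype]
    if cal.empty:
        raise ValueError(f"calibrator genotype {calibrator_genotype!r} absent")
    cal_dct = cal.groupby("gene")["dct"].mean()
    targets["ddct"] = targets["dct"] - cal_dct.reindex(targets["gene"]).to_numpy()
    targets = targets.dropna(subset=["ddct"])
    targets["value"] = 2.0 ** (-targets["ddct"])
    targets["log2_value"] = -targets["ddct"]
    return targets[["genotype", "gene", "replicate", "value", "log2_value"]].reset_index(
        drop=True
    )


def median_center(values: Sequence[float]) -> np.ndarray:
    """Center relative-expression values on their median, log2 scale.

    Input is positive expression values; output is log2(value) minus
    the median log2(value), so the output median is exactly 0.
    """
    x = np.asarray(values, dtype=float)
    if (x <= 0).any():
        raise ValueError("expression values must be positive")
    logx = np.log2(x)
    return logx - np.median(logx)


def median_center_table(
    rel: pd.DataFrame, by: Sequence[str] = ("gene", "background")
) -> pd.DataFrame:
    """Apply median centering within groups of a ddct output table.

    Adds a ``centered_log2`` column; ``by`` names the columns defining
    each strain-background / replicate set (default gene x background;
    falls back to gene alone when no background column exists).
    """
    by = [c for c in by if c in rel.columns]
    if not by:
        raise ValueError("no grouping columns present in the table")
    out = rel.copy()
    out["centered_log2"] = (
        out.groupby(by, sort=False)["log2_value"].transform(lambda v: v - v.median())
    )
    return out


def regulon_wilcoxon(
    expr_a: pd.Series,
    expr_b: pd.Series,
    regulon: Optional[GeneSet] = None,
) -> Optional[float]:
    """Paired Wilcoxon signed-rank p for a regulon between genotypes.

    ``expr_a`` and ``expr_b`` map gene -> expression measure for the
    two genotypes; pairing is by gene, restricted to ``regulon.members``
    when a regulon is given.  Returns the two-sided p (exact for n <=
    25 when free of ties/zeros), 1.0 for identical vectors, or None
    when fewer than 2 paired genes are available (untestable).
    """
    genes = expr_a.index.intersection(expr_b.index)
    if regulon is not None:
        genes = genes.intersection(regulon.members)
    if len(genes) < 2:
        return None
    diff = expr_a.loc[genes].to_numpy(dtype=float) - expr_b.loc[genes].to_numpy(dtype=float)
    if np.all(diff == 0):
        return 1.0
    method = "exact" if len(diff) <= 25 and np.all(diff != 0) else "auto"
    return float(stats.wilcoxon(diff, alternative="two-sided", method=method).pvalue)
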