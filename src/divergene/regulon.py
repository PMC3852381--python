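"""Directional expression-divergence test for gene groups.

The question: do the significantly differentially expressed members of
a regulon shift coherently in one direction between two populations?
The statistic is either the sum of signs of the members' log2 fold
changes (``sign_sum``) or the sum of the log2 fold changes themselves
(``ratio_sum``), taken over regulon members significant at an adjusted-p
cutoff.  Its null distribution comes from random gene groups of the
same size drawn from all significantly DE genes, and the empirical
two-sided p value is the add-one-smoothed proportion of null groups at
least as extreme (in absolute value) as the observed statistic.

Both statistic modes are provided because the procedure is described
with the ratio sum while the reported table is annotated with the sign
sum; ``sign_sum`` is the default and results carry the mode used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from divergene.expression import bh_adjust

__all__ = [
    "GeneSet",
    "DirectionalResult",
    "directional_statistic",
    "directional_test",
    "screen_gene_sets",
    "results_table",
]

MODES = ("sign_sum", "ratio_sum")


@dataclass(frozen=True)
class GeneSet:
    """A named regulon / GO term: an identifier, free-text annotation
    and a set of member gene IDs."""

    id: str
    members: frozenset
    annotation: str = ""

    def __init__(self, id: str, members: Iterable[str], annotation: str = "") -> None:
        if not id:
            raise ValueError("gene set needs a nonempty id")
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {id!r} is empty")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "annotation", annotation)


@dataclass
class DirectionalResult:
    """Outcome of the directional test for one gene set.

    ``direction`` is ``up_in_a`` / ``up_in_b`` (the group with elevated
    expression, given log2fc oriented a/b) or ``none``; untestable sets
    (no significant members) carry ``p_nominal = None``.
    """

    regulon_id: str
    n_significant_members: int
    statistic: Optional[float]
    direction: str
    p_nominal: Optional[float]
    p_adjusted: Optional[float] = None
    mode: str = "sign_sum"
    annotation: str = ""


def _significant(de: pd.DataFrame, alpha: float) -> pd.Series:
    """log2fc of genes significant at adjusted p < alpha."""
    if "padj" not in de.columns or "log2FoldChange" not in de.columns:
        raise ValueError("DE table needs 'padj' and 'log2FoldChange' columns")
    keep = de["padj"].to_numpy() < alpha
    return de.loc[keep, "log2FoldChange"]


def _statistic(values: np.ndarray, mode: str) -> float:
    if mode == "sign_sum":
        return float(np.sign(values).sum())
    if mode == "ratio_sum":
        return float(values.sum())
    raise ValueError(f"unknown statistic mode {mode!r}; expected one of {MODES}")


def directional_statistic(
    de: pd.DataFrame, regulon: GeneSet, alpha: float = 0.05, mode: str = "sign_sum"
) -> Tuple[Optional[float], int]:
    """Observed directional statistic and the member count it used.

    Only regulon members with adjusted p < ``alpha`` enter the sum; a
    regulon with no significant member returns ``(None, 0)``.
    """
    sig = _significant(de, alpha)
    members = sig.index.intersection(regulon.members)
    if len(members) == 0:
        return None, 0
    return _statistic(sig.loc[members].to_numpy(), mode), len(members)


def directional_test(
    de: pd.DataFrame,
    regulon: GeneSet,
    alpha: float = 0.05,
    mode: str = "sign_sum",
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> DirectionalResult:
    """Resampling test for coherent directional change of one regulon.

    Null groups of the regulon's effective size are drawn without
    replacement from all genes significant at adjusted p < ``alpha``;
    the two-sided empirical p is
    ``(1 + #{|null stat| >= |observed|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = _significant(de, alpha)
    members = sig.index.intersection(regulon.members)
    k = len(members)
    if k == 0:
        return DirectionalResult(
            regulon.id, 0, None, "none", None, mode=mode, annotation=regulon.annotation
        )
    observed = _statistic(sig.loc[members].to_numpy(), mode)
    universe = sig.to_numpy()
    if k == len(universe):
        import warnings

        warnings.warn(
            f"regulon {regulon.id!r} covers the whole significant-gene universe; p = 1"
        )
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(universe, size=k, replace=False)
        null[i] = _statistic(draw, mode)
    # boundary ties count as "as extreme"; the tolerance guards against
    # summation-order floating-point noise on exact ties
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    if observed > 0:
        direction = "up_in_a"
    elif observed < 0:
        direction = "up_in_b"
    else:
        direction = "none"
    return DirectionalResult(
        regulon.id, k, observed, direction, p, mode=mode, annotation=regulon.annotation
    )


def screen_gene_sets(
    de: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.05,
    mode: str = "sign_sum",
    n_perm: int = 10_000,
    seed: int = 0,
) -> List[DirectionalResult]:
    """Run the directional test over many gene sets, BH-adjusted.

    The adjustment spans the testable sets (those with at least one
    significant member); untestable sets are returned with null p
    values so the caller sees the full input list.
    """
    rng = np.random.default_rng(seed)
    results = [
        directional_test(de, gs, alpha=alpha, mode=mode, n_perm=n_perm, seed=rng)
        for gs in gene_sets
    ]
    testable = [r for r in results if r.p_nominal is not None]
    adj = bh_adjust([r.p_nominal for r in testable])
    for r, a in zip(testable, adj):
        r.p_adjusted = float(a)
    return results


def results_table(
    results: Sequence[DirectionalResult],
    group_a_label: str = "A",
    group_b_label: str = "B",
) -> pd.DataFrame:
    """Tabulate directional results with human-readable direction labels."""
    label = {"up_in_a": group_a_label, "up_in_b": group_b_label, "none": "none"}
    return pd.DataFrame(
        {
            "group": [r.regulon_id for r in results],
            "annotation": [r.annotation for r in results],
            "n_significant": [r.n_significant_members for r in results],
            "statistic": [r.statistic for r in results],
            "mode": [r.mode for r in results],
            "upregulated": [label[r.direction] for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
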