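"""Differential activity testing, miRNA-target correlation, enrichment.

Conventions follow the analysis defaults: Wilcoxon rank-sum with
Benjamini-Hochberg FDR for differential activity; Pearson correlation with
an |r| > 0.3 and Bonferroni-adjusted p < 0.05 dual threshold for
miRNA-target classification; upper-tail hypergeometric tests with BH
adjustment for gene-set enrichment.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ActivityMatrix

PROMOTING = "promoting"
SUPPRESSING = "suppressing"
NOT_SIGNIFICANT = "not_significant"


def _ranksum_test(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; returns (U of the first group, p).

    Exact null distribution when min(n1, n2) <= 8 and the pooled data is
    tie-free; tie-corrected normal approximation (with continuity
    correction) otherwise. Fully tied data gives p = 1.
    """
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return len(x) * len(y) / 2.0, 1.0
    if min(len(x), len(y)) <= 8 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def differential_activity(
    act: ActivityMatrix, labels: pd.Series, fdr: float = 0.1
) -> pd.DataFrame:
    """Per-miRNA Wilcoxon rank-sum test between two labeled spot groups.

    ``labels`` maps barcodes to exactly two group labels; the first group in
    sorted label order is "A". Returns one row per miRNA with U, p, the
    BH-adjusted q over all tested miRNAs, the rank-biserial effect size
    2U/(n1*n2) - 1, and the direction of the median shift.
    """
    labels = labels.loc[labels.index.intersection(act.barcodes)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"labels must define exactly 2 groups, got {groups}")
    ga, gb = groups
    idx_a = labels.index[labels == ga]
    idx_b = labels.index[labels == gb]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("both groups need >= 3 spots")
    va = act.values.loc[idx_a].to_numpy(dtype=float)
    vb = act.values.loc[idx_b].to_numpy(dtype=float)
    n1, n2 = len(idx_a), len(idx_b)
    rows = []
    for j, name in enumerate(act.mirna_ids):
        U, p = _ranksum_test(va[:, j], vb[:, j])
        effect = 2.0 * U / (n1 * n2) - 1.0
        med_a, med_b = np.median(va[:, j]), np.median(vb[:, j])
        direction = "up_in_A" if med_a > med_b else ("up_in_B" if med_b > med_a else "none")
        rows.append(
            {
                "mirna": name,
                "n_A": n1,
                "n_B": n2,
                "U": U,
                "p": p,
                "effect_rank_biserial": effect,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    out.attrs["groups"] = {"A": ga, "B": gb}
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(p, method="fdr_bh")[1]


def mirna_target_correlation(
    act: ActivityMatrix,
    expr: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]],
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation over spots for each (miRNA, target gene) pair.

    ``expr`` is a spot x gene matrix sharing barcodes with ``act``. The
    Bonferroni family is all pairs tested in this call. A pair is
    ``promoting`` when r > r_min with adjusted p < alpha, ``suppressing``
    when r < -r_min likewise, otherwise ``not_significant``. Constant
    vectors leave r undefined and the pair flagged.
    """
    shared = act.barcodes.intersection(expr.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared spots")
    pairs = list(pairs)
    for mir, gene in pairs:
        if mir not in act.mirna_ids:
            raise KeyError(f"miRNA {mir!r} not in activity matrix")
        if gene not in expr.columns:
            raise KeyError(f"gene {gene!r} not in expression matrix")
    m_family = len(pairs)
    rows = []
    for mir, gene in pairs:
        x = act.values.loc[shared, mir].to_numpy(dtype=float)
        y = expr.loc[shared, gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {
                    "mirna": mir,
                    "gene": gene,
                    "r": np.nan,
                    "p": np.nan,
                    "p_bonferroni": np.nan,
                    "classification": NOT_SIGNIFICANT,
                    "constant_input": True,
                }
            )
            continue
        r, p = stats.pearsonr(x, y)
        p_adj = min(1.0, p * m_family)
        if r > r_min and p_adj < alpha:
            cls = PROMOTING
        elif r < -r_min and p_adj < alpha:
            cls = SUPPRESSING
        else:
            cls = NOT_SIGNIFICANT
        rows.append(
            {
                "mirna": mir,
                "gene": gene,
                "r": float(r),
                "p": float(p),
                "p_bonferroni": float(p_adj),
                "classification": cls,
                "constant_input": False,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = m_family
    out.attrs["r_min"] = r_min
    out.attrs["alpha"] = alpha
    return out


def enrich(
    query_genes: Sequence[str],
    genesets: Dict[str, Sequence[str]],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list against sets.

    Sets are intersected with the universe first; p is the probability of
    drawing >= k set members in ``len(query)`` draws without replacement
    from a universe of N containing K set members. BH adjustment across
    all sets tested.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe_set:
        extra = sorted(query - universe_set)
        raise ValueError(f"query genes outside the universe: {extra[:5]}")
    N = len(universe_set)
    n = len(query)
    rows = []
    for name, members in genesets.items():
        members_u = set(members) & universe_set
        K = len(members_u)
        k = len(query & members_u)
        # P(X >= k), hypergeom(N, K, n); sf(k-1) is the upper tail incl. k
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"gene_set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["p_adj"] < alpha
    return out
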