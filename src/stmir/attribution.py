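"""Dominant-cell-type assignment and cell-type-level miRNA summaries.

Dominance is decided from the abundance matrix alone — activity values are
only joined afterward — so attribution can never leak prediction signal
into the assignment step.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import ActivityMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


def assign_dominant(ab: pd.DataFrame, min_purity: float = 0.0) -> pd.DataFrame:
    """Assign each spot its dominant cell type, or UNASSIGNED.

    Abundances are row-normalized to sum 1 (scale-invariant). A spot is
    UNASSIGNED when its top share falls below ``min_purity``, when the top
    two shares tie exactly, or when the row is all-zero.

    Returns a DataFrame indexed by barcode with columns ``dominant_type``
    and ``purity`` (the top normalized share; 0 for all-zero rows).
    """
    v = ab.to_numpy(dtype=float)
    if v.size and v.min() < 0:
        raise ValueError("abundances must be non-negative")
    row_sum = v.sum(axis=1)
    zero_rows = row_sum == 0
    if zero_rows.any():
        logger.warning("%d all-zero abundance row(s) left UNASSIGNED", zero_rows.sum())
    safe = np.where(zero_rows, 1.0, row_sum)
    shares = v / safe[:, None]
    top_idx = shares.argmax(axis=1)
    top = shares[np.arange(len(shares)), top_idx]
    # exact tie of the top two shares -> unassigned
    shares_sorted = np.sort(shares, axis=1)
    tied = shares.shape[1] > 1
    tie_mask = (shares_sorted[:, -1] == shares_sorted[:, -2]) if tied else np.zeros(len(shares), bool)
    unassigned = zero_rows | tie_mask | (top < min_purity)
    dominant = np.where(unassigned, UNASSIGNED, ab.columns.to_numpy()[top_idx])
    purity = np.where(zero_rows, 0.0, top)
    return pd.DataFrame(
        {"dominant_type": dominant, "purity": purity}, index=ab.index
    )


def celltype_mirna_profile(
    act: ActivityMatrix,
    da: pd.DataFrame,
    min_spots: int = 10,
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-(cell type, miRNA) median activity, consistency, and rank.

    For every cell type dominating at least ``min_spots`` spots:
    the median activity over its dominated spots, the fraction of those
    spots where the miRNA exceeds the spot's own median activity
    (``consistency``), and a rank by median (1 = highest, ties broken by
    miRNA name so ranks form a permutation). Cell types below ``min_spots``
    are excluded and returned separately.
    """
    shared = act.barcodes.intersection(da.index)
    if len(shared) == 0:
        raise ValueError("no shared barcodes between activity and assignment")
    values = act.values.loc[shared]
    dom = da.loc[shared, "dominant_type"]
    spot_median = values.median(axis=1)
    exceeds = values.gt(spot_median, axis=0)

    rows = []
    excluded: List[str] = []
    for ct, idx in dom.groupby(dom).groups.items():
        if ct == UNASSIGNED:
            continue
        if len(idx) < min_spots:
            excluded.append(str(ct))
            continue
        med = values.loc[idx].median(axis=0)
        cons = exceeds.loc[idx].mean(axis=0)
        order = sorted(
            med.index, key=lambda name: (-med[name], name)
        )
        rank = pd.Series({name: i + 1 for i, name in enumerate(order)})
        for name in med.index:
            rows.append(
                {
                    "cell_type": ct,
                    "mirna": name,
                    "median_activity": float(med[name]),
                    "consistency": float(cons[name]),
                    "rank": int(rank[name]),
                    "n_spots": int(len(idx)),
                }
            )
    if not rows:
        raise ValueError(f"no cell type dominates >= {min_spots} spots")
    return pd.DataFrame(rows), excluded


def rank_mirnas_per_context(act: ActivityMatrix) -> List[str]:
    """miRNAs sorted by mean activity over all spots, descending.

    Ties break alphabetically so the ordering is stable across runs.
    """
    if act.values.size == 0:
        raise ValueError("empty activity matrix")
    means = act.values.mean(axis=0)
    return sorted(means.index, key=lambda name: (-means[name], name))


def conserved_mirnas(
    rankings: Dict[str, Sequence[str]], top_k: int = 40
) -> Tuple[Set[str], pd.DataFrame]:
    """miRNAs in the top-``top_k`` of every context's ranking.

    Returns the conserved set and a per-miRNA rank table (rows = miRNAs in
    any top-k, columns = contexts, values = 1-based rank or NaN).
    """
    if len(rankings) < 2:
        raise ValueError("need at least 2 contexts")
    tops = {}
    for ctx, ranked in rankings.items():
        if not len(ranked):
            raise ValueError(f"empty ranking list for context {ctx!r}")
        tops[ctx] = list(ranked)[:top_k]
    conserved = set.intersection(*(set(t) for t in tops.values()))
    union = sorted(set().union(*(set(t) for t in tops.values())))
    table = pd.DataFrame(index=union, columns=list(rankings), dtype=float)
    for ctx, ranked in rankings.items():
        pos = {name: i + 1 for i, name in enumerate(ranked)}
        table[ctx] = [pos.get(name, np.nan) for name in union]
    return conserved, table
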