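"""Harmonize, rank-normalize and integrate two paired bulk cohorts.

The pipeline removes monotone batch effects between cohorts:

1. harmonize miRNA names, keep shared features, drop near-all-zero features,
   ``log(x+1)``-transform;
2. intra-sample percentile ranking followed by a per-feature rank-based
   inverse normal transform (INT), performed within each cohort;
3. column-wise concatenation of the two cohorts and per-feature min-max
   scaling to [0, 1].

Because every step from the ranking onward depends only on within-sample and
within-cohort orderings, any strictly increasing per-sample distortion of the
raw input leaves the integrated output bit-identical.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExprMatrix, IntegratedTrainingSet

logger = logging.getLogger(__name__)

_ARM_SUFFIX = re.compile(r"-(3p|5p)$", flags=re.IGNORECASE)


def canonical_mirna_name(name: str) -> str:
    """Strip a trailing arm designator (-3p/-5p) and lowercase the stem."""
    return _ARM_SUFFIX.sub("", name.strip()).lower()


def harmonize_mirna_names(m: ExprMatrix) -> ExprMatrix:
    """Collapse arm variants of the same miRNA to a single median row.

    Rows whose names differ only by a ``-3p``/``-5p`` suffix (or by case)
    are merged; the merged row is the element-wise median of its members.
    """
    if m.modality != "miRNA":
        raise ValueError("harmonize_mirna_names requires a miRNA matrix")
    if m.n_features == 0:
        raise ValueError("no miRNA features")
    canon = m.values.index.map(canonical_mirna_name)
    collapsed = m.values.groupby(canon, sort=False).median()
    collapsed.index.name = m.values.index.name
    return m.with_values(collapsed, stage=m.stage)


def filter_common_features(
    a: ExprMatrix,
    b: ExprMatrix,
    max_zero_frac: float = 0.9,
) -> Tuple[ExprMatrix, ExprMatrix]:
    """Restrict both cohorts to shared features, dropping near-all-zero ones.

    A feature is dropped from *both* cohorts if its zero-fraction exceeds
    ``max_zero_frac`` in either cohort.
    """
    if a.modality != b.modality:
        raise ValueError("cohorts must share a modality")
    if not 0.0 <= max_zero_frac <= 1.0:
        raise ValueError("max_zero_frac must be in [0,1]")
    common = a.feature_ids.intersection(b.feature_ids)
    if len(common) == 0:
        raise ValueError("no shared features")
    # keep a deterministic order: a's input order restricted to the intersection
    common = a.feature_ids[a.feature_ids.isin(common)]
    va = a.values.loc[common]
    vb = b.values.loc[common]
    zf_a = (va == 0).mean(axis=1)
    zf_b = (vb == 0).mean(axis=1)
    keep = (zf_a <= max_zero_frac) & (zf_b <= max_zero_frac)
    if not keep.any():
        raise ValueError("no shared features")
    kept = common[keep.to_numpy()]
    return (
        a.with_values(va.loc[kept], stage=a.stage),
        b.with_values(vb.loc[kept], stage=b.stage),
    )


def log_transform(m: ExprMatrix, base: int = 2) -> ExprMatrix:
    """Apply ``log_base(x + 1)`` to a raw matrix."""
    m.require_stage("raw")
    if base not in (2, 10):
        raise ValueError("base must be 2 or 10")
    v = m.values.to_numpy(dtype=float)
    if v.size and v.min() < 0:
        i, j = np.unravel_index(int(np.argmin(v)), v.shape)
        raise ValueError(
            f"negative expression value at feature {m.feature_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}"
        )
    out = np.log1p(v) / np.log(base)
    return m.with_values(
        pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), stage="log"
    )


def _rank_quantiles(x: np.ndarray, axis: int) -> np.ndarray:
    """Average-tie ranks along ``axis`` mapped to quantiles r/(n+1)."""
    n = x.shape[axis]
    r = stats.rankdata(x, axis=axis, method="average")
    return r / (n + 1)


def intra_sample_percentile_rank(m: ExprMatrix) -> ExprMatrix:
    """Replace each sample's values with their percentile ranks r/(n+1)."""
    m.require_stage("log")
    if m.n_features < 2:
        raise ValueError("ranking undefined for n=1")
    q = _rank_quantiles(m.values.to_numpy(dtype=float), axis=0)
    return m.with_values(
        pd.DataFrame(q, index=m.feature_ids, columns=m.sample_ids),
        stage="percentile",
    )


def inverse_normal_transform(m: ExprMatrix) -> ExprMatrix:
    """Per-feature rank-based inverse normal transform across samples.

    Each feature's values are re-ranked across samples (average ties),
    converted to quantiles r/(n+1), and mapped through the standard normal
    quantile function, so every feature follows N(0,1) across samples.
    """
    m.require_stage("percentile")
    if m.n_samples < 2:
        raise ValueError("inverse normal transform requires at least 2 samples")
    q = _rank_quantiles(m.values.to_numpy(dtype=float), axis=1)
    z = stats.norm.ppf(q)
    return m.with_values(
        pd.DataFrame(z, index=m.feature_ids, columns=m.sample_ids), stage="z"
    )


def integrate_cohorts(a: ExprMatrix, b: ExprMatrix) -> ExprMatrix:
    """Concatenate two z-stage cohorts by samples, recording cohort labels."""
    a.require_stage("z")
    b.require_stage("z")
    if list(a.feature_ids) != list(b.feature_ids):
        raise ValueError("feature order mismatch between cohorts")
    overlap = a.sample_ids.intersection(b.sample_ids)
    if len(overlap):
        raise ValueError(f"duplicate sample_id across cohorts: {list(overlap[:5])}")
    values = pd.concat([a.values, b.values], axis=1)
    sample_cohorts = pd.Series(
        [a.cohort] * a.n_samples + [b.cohort] * b.n_samples, index=values.columns
    )
    return ExprMatrix(
        values=values,
        modality=a.modality,
        cohort=f"{a.cohort}+{b.cohort}",
        stage="z",
        sample_cohorts=sample_cohorts,
    )


def minmax_scale(
    m: ExprMatrix,
    params: Optional[pd.DataFrame] = None,
) -> Tuple[ExprMatrix, pd.DataFrame]:
    """Per-feature min-max scale to [0, 1].

    If ``params`` (a DataFrame with columns ``min``/``max`` indexed by
    feature) is given, those frozen bounds are applied and the result is
    clipped to [0, 1]; otherwise bounds are computed from ``m`` and returned.
    A constant feature maps to all zeros.
    """
    if params is None:
        m.require_stage("z")
        lo = m.values.min(axis=1)
        hi = m.values.max(axis=1)
        params = pd.DataFrame({"min": lo, "max": hi})
        clip = False
    else:
        missing = params.index.difference(m.feature_ids)
        if len(missing):
            raise ValueError(
                f"scaler params given for features absent from matrix: "
                f"{list(missing[:5])}"
            )
        params = params.loc[m.feature_ids]
        clip = True
    lo = params["min"].to_numpy()[:, None]
    hi = params["max"].to_numpy()[:, None]
    span = hi - lo
    constant = (span == 0).ravel()
    if constant.any():
        logger.warning(
            "%d constant feature(s) mapped to 0.0 under min-max scaling",
            int(constant.sum()),
        )
    safe_span = np.where(span == 0, 1.0, span)
    scaled = (m.values.to_numpy(dtype=float) - lo) / safe_span
    scaled[constant, :] = 0.0
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    out = m.with_values(
        pd.DataFrame(scaled, index=m.feature_ids, columns=m.sample_ids),
        stage="scaled01",
    )
    return out, params


def minmax_unscale(m: ExprMatrix, params: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`minmax_scale` with stored params (constant rows -> min)."""
    params = params.loc[m.feature_ids]
    lo = params["min"].to_numpy()[:, None]
    hi = params["max"].to_numpy()[:, None]
    return pd.DataFrame(
        m.values.to_numpy() * (hi - lo) + lo,
        index=m.feature_ids,
        columns=m.sample_ids,
    )


def build_training_set(
    mrna: ExprMatrix,
    mirna: ExprMatrix,
    x_scaler: pd.DataFrame,
    y_scaler: pd.DataFrame,
    feature_restrict: Optional[Sequence[str]] = None,
) -> IntegratedTrainingSet:
    """Align samples and orient to sample x feature for model training."""
    mrna.require_stage("scaled01")
    mirna.require_stage("scaled01")
    shared = mrna.sample_ids.intersection(mirna.sample_ids)
    if len(shared) < 10:
        raise ValueError("insufficient paired samples")
    shared = mrna.sample_ids[mrna.sample_ids.isin(shared)]
    genes = mrna.feature_ids
    if feature_restrict is not None:
        restrict = pd.Index(feature_restrict)
        missing = restrict.difference(genes)
        if len(missing):
            logger.warning(
                "feature_restrict genes absent from training matrix: %s",
                list(missing),
            )
        genes = genes[genes.isin(restrict)]
        x_scaler = x_scaler.loc[genes]
    X = mrna.values.loc[genes, shared].T
    Y = mirna.values.loc[:, shared].T
    cohorts = (
        mrna.sample_cohorts.loc[shared]
        if mrna.sample_cohorts is not None
        else pd.Series(mrna.cohort, index=shared)
    )
    return IntegratedTrainingSet(
        X=X, Y=Y, x_scaler=x_scaler, y_scaler=y_scaler, cohort_of_sample=cohorts
    )


def rank_int_pipeline(m: ExprMatrix, base: int = 2) -> ExprMatrix:
    """Run log -> intra-sample percentile -> per-feature INT on one cohort."""
    return inverse_normal_transform(intra_sample_percentile_rank(log_transform(m, base)))


def integrate_pair(
    mrna_a: ExprMatrix,
    mirna_a: ExprMatrix,
    mrna_b: ExprMatrix,
    mirna_b: ExprMatrix,
    max_zero_frac: float = 0.9,
    feature_restrict: Optional[Sequence[str]] = None,
) -> IntegratedTrainingSet:
    """Full two-cohort integration: harmonize, filter, rank-INT, scale, align."""
    mirna_a = harmonize_mirna_names(mirna_a)
    mirna_b = harmonize_mirna_names(mirna_b)
    mrna_a, mrna_b = filter_common_features(mrna_a, mrna_b, max_zero_frac)
    mirna_a, mirna_b = filter_common_features(mirna_a, mirna_b, max_zero_frac)
    mrna_z = integrate_cohorts(rank_int_pipeline(mrna_a), rank_int_pipeline(mrna_b))
    mirna_z = integrate_cohorts(rank_int_pipeline(mirna_a), rank_int_pipeline(mirna_b))
    mrna_s, x_scaler = minmax_scale(mrna_z)
    mirna_s, y_scaler = minmax_scale(mirna_z)
    return build_training_set(
        mrna_s, mirna_s, x_scaler, y_scaler, feature_restrict=feature_restrict
    )
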