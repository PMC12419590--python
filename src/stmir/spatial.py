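"""Visium-style spot matrix ingestion, QC, normalization and spot prediction.

Spots are treated as miniature bulk samples: after count normalization and
log transform, the spot matrix is re-encoded with the same rank ->
inverse-normal -> min-max pipeline used on the bulk training data (computed
within the spatial dataset) and pushed through the trained per-miRNA
regressors.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import datafusion
from .regression import ModelBundle, predict
from .types import ActivityMatrix, ExprMatrix, SpotDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# loading


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(dirpath: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        p = dirpath / (stem + suffix)
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def _dedupe_sum(counts: np.ndarray, gene_ids: pd.Index) -> Tuple[np.ndarray, pd.Index]:
    """Sum spot x gene columns that share a gene symbol."""
    if not gene_ids.duplicated().any():
        return counts, gene_ids
    df = pd.DataFrame(counts.T, index=gene_ids)
    summed = df.groupby(level=0, sort=False).sum()
    return summed.to_numpy().T, pd.Index(summed.index)


def load_visium(path, positions: Optional[str] = None) -> SpotDataset:
    """Load a 10x MTX triplet directory or a 10x HDF5 feature-barcode matrix.

    The on-disk layout (gene x barcode) is transposed to spot x gene.
    Duplicate gene symbols are collapsed by summation. ``positions`` may
    point at a tissue-position CSV (barcode, ..., array col/row in the last
    two columns); without it, coords are absent and a warning is logged.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find(path, "matrix.mtx")
        barcodes_f = _find(path, "barcodes.tsv")
        features_f = _find(path, "features.tsv")
        mat = spio.mmread(str(mtx))
        with _open_maybe_gz(barcodes_f) as fh:
            barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gz(features_f) as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        # features.tsv: id, symbol, type — prefer the symbol column if present
        genes = [r[1] if len(r) > 1 else r[0] for r in rows]
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            grp = fh["matrix"] if "matrix" in fh else fh[list(fh.keys())[0]]
            data = grp["data"][...]
            indices = grp["indices"][...]
            indptr = grp["indptr"][...]
            shape = tuple(grp["shape"][...])
            mat = sparse.csc_matrix((data, indices, indptr), shape=shape)
            barcodes = [b.decode() for b in grp["barcodes"][...]]
            feat = grp["features"] if "features" in grp else grp
            name_ds = feat["name"] if "name" in feat else feat["genes"]
            genes = [g.decode() for g in name_ds[...]]
    else:
        raise ValueError(f"unrecognized Visium input: {path}")

    mat = sparse.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix dims {mat.shape} do not match {len(genes)} features x "
            f"{len(barcodes)} barcodes"
        )
    counts = np.asarray(mat.T.todense())
    counts, gene_ids = _dedupe_sum(counts, pd.Index(genes))

    coords = None
    if positions is not None:
        pos = pd.read_csv(positions, header=None, index_col=0)
        pos = pos.reindex(barcodes)
        coords = pos.iloc[:, -2:].to_numpy(dtype=float)
    else:
        logger.warning("no tissue-position table supplied; coords absent")
    return SpotDataset(
        counts=counts, barcodes=pd.Index(barcodes), gene_ids=gene_ids, coords=coords
    )


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    """Deterministic record of every QC removal, by reason."""

    n_spots_in: int
    n_genes_in: int
    spots_removed_total_counts: int = 0
    spots_removed_min_counts: int = 0
    spots_removed_min_genes: int = 0
    genes_removed_min_cells: int = 0
    n_spots_out: int = 0
    n_genes_out: int = 0
    order: tuple = ("spot_filters", "gene_filter")
    thresholds: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_spots_in": self.n_spots_in,
            "n_genes_in": self.n_genes_in,
            "spots_removed_total_counts": self.spots_removed_total_counts,
            "spots_removed_min_counts": self.spots_removed_min_counts,
            "spots_removed_min_genes": self.spots_removed_min_genes,
            "genes_removed_min_cells": self.genes_removed_min_cells,
            "n_spots_out": self.n_spots_out,
            "n_genes_out": self.n_genes_out,
            "order": list(self.order),
            "thresholds": self.thresholds,
        }


def qc_filter(
    sd: SpotDataset,
    max_total_counts: Optional[float] = None,
    min_cells_per_gene: Optional[int] = 10,
    min_counts_per_spot: Optional[float] = None,
    min_genes_per_spot: Optional[int] = None,
    gene_filter_basis: str = "post_spot_filter",
) -> Tuple[SpotDataset, QCReport]:
    """Remove outlier spots and rarely detected genes.

    Spot filters run first (total counts strictly above ``max_total_counts``
    removed, then spot-level minima); the gene detection floor is evaluated
    on the spot-filtered matrix by default, or on the original matrix with
    ``gene_filter_basis="pre_spot_filter"``. The chosen basis is recorded in
    the QC report. ``None`` disables a threshold.
    """
    if gene_filter_basis not in ("post_spot_filter", "pre_spot_filter"):
        raise ValueError(f"unknown gene_filter_basis {gene_filter_basis!r}")
    report = QCReport(
        n_spots_in=sd.n_spots,
        n_genes_in=sd.n_genes,
        thresholds={
            "max_total_counts": max_total_counts,
            "min_cells_per_gene": min_cells_per_gene,
            "min_counts_per_spot": min_counts_per_spot,
            "min_genes_per_spot": min_genes_per_spot,
            "gene_filter_basis": gene_filter_basis,
        },
    )
    totals = sd.total_counts
    keep_spot = np.ones(sd.n_spots, dtype=bool)
    if max_total_counts is not None:
        bad = totals > max_total_counts
        report.spots_removed_total_counts = int(bad.sum())
        keep_spot &= ~bad
    if min_counts_per_spot is not None:
        bad = (totals < min_counts_per_spot) & keep_spot
        report.spots_removed_min_counts = int(bad.sum())
        keep_spot &= ~bad
    if min_genes_per_spot is not None:
        bad = (sd.genes_detected < min_genes_per_spot) & keep_spot
        report.spots_removed_min_genes = int(bad.sum())
        keep_spot &= ~bad
    if not keep_spot.any():
        raise ValueError("QC eliminated all spots")
    counts = sd.counts[keep_spot]
    keep_gene = np.ones(sd.n_genes, dtype=bool)
    if min_cells_per_gene is not None:
        basis = counts if gene_filter_basis == "post_spot_filter" else sd.counts
        detected_in = (basis > 0).sum(axis=0)
        keep_gene = detected_in >= min_cells_per_gene
        report.genes_removed_min_cells = int((~keep_gene).sum())
    out = SpotDataset(
        counts=counts[:, keep_gene],
        barcodes=sd.barcodes[keep_spot],
        gene_ids=sd.gene_ids[keep_gene],
        coords=sd.coords[keep_spot] if sd.coords is not None else None,
    )
    report.n_spots_out = out.n_spots
    report.n_genes_out = out.n_genes
    return out, report


# ---------------------------------------------------------------------------
# normalization and features


def normalize_st(sd: SpotDataset, target_sum: float = 1e4) -> ExprMatrix:
    """Scale each spot to ``target_sum`` total counts, then log10(x+1)."""
    totals = sd.total_counts.astype(float)
    if (totals == 0).any():
        bad = sd.barcodes[totals == 0]
        raise ValueError(f"zero-count spot(s) present (QC should remove): {list(bad[:5])}")
    scaled = sd.counts / totals[:, None] * target_sum
    logged = np.log10(scaled + 1.0)
    values = pd.DataFrame(logged.T, index=sd.gene_ids, columns=sd.barcodes)
    return ExprMatrix(values=values, modality="mRNA", cohort="ST", stage="log")


def select_hvg(m: ExprMatrix, n: int = 2000) -> List[str]:
    """Top-``n`` genes by variance of the log-normalized values, in rank order."""
    m.require_stage("log")
    if m.n_samples < 2:
        raise ValueError("highly variable gene selection requires >= 2 spots")
    var = m.values.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")
    top = order[: min(n, len(order))]
    return list(m.feature_ids[top])


def prepare_features_for_model(
    m: ExprMatrix, model: ModelBundle, encoding: str = "rank-int"
) -> pd.DataFrame:
    """Encode an ST log matrix onto the model's [0, 1] feature scale.

    The matrix is restricted and ordered to ``model.feature_genes``, then
    (default ``rank-int`` encoding) pushed through intra-spot percentile
    ranking, per-gene inverse-normal transform across spots, and per-gene
    min-max scaling — the same encoding the training data received, computed
    within the spatial dataset. The ``lognorm-scale`` alternative skips the
    rank steps and min-max scales the log values directly.
    """
    m.require_stage("log")
    missing = pd.Index(model.feature_genes).difference(m.feature_ids)
    if len(missing):
        raise ValueError(
            f"{len(missing)} model feature gene(s) absent from the ST matrix "
            f"(e.g. {list(missing[:5])}); retrain with feature_restrict set to "
            "the available ST genes"
        )
    sub = m.with_values(m.values.loc[model.feature_genes], stage="log")
    if encoding == "rank-int":
        enc = datafusion.inverse_normal_transform(
            datafusion.intra_sample_percentile_rank(sub)
        )
        scaled, _ = datafusion.minmax_scale(enc)
    elif encoding == "lognorm-scale":
        v = sub.values
        lo = v.min(axis=1)
        hi = v.max(axis=1)
        span = (hi - lo).replace(0, 1.0)
        scaled_v = v.sub(lo, axis=0).div(span, axis=0).clip(0.0, 1.0)
        scaled = ExprMatrix(scaled_v, "mRNA", sub.cohort, "scaled01")
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return scaled.values.T  # spots x genes in model order


def predict_spot_activity(
    model: ModelBundle, m: ExprMatrix, encoding: str = "rank-int"
) -> ActivityMatrix:
    """Predict per-spot miRNA activity from a QC'd, log-normalized ST matrix."""
    X = prepare_features_for_model(m, model, encoding=encoding)
    act = predict(model, X)
    return ActivityMatrix(
        values=act,
        model_id=model.model_id,
        params={"encoding": encoding, "n_feature_genes": len(model.feature_genes)},
    )
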