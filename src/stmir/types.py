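"""Core domain types shared across the stmir modules.

Expression data travels as :class:`ExprMatrix` (features in rows, samples in
columns) with an explicit processing ``stage`` label so that every operation
can reject input at the wrong stage instead of silently recomputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "log", "percentile", "z", "scaled01")

MODALITIES = ("mRNA", "miRNA")


class StageError(ValueError):
    """Raised when an operation receives an ExprMatrix at the wrong stage."""


@dataclass
class ExprMatrix:
    """A feature x sample expression matrix with processing provenance.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and sample IDs as columns.
    modality
        ``"mRNA"`` or ``"miRNA"``.
    cohort
        Label of the originating cohort (integrated matrices get a combined
        label plus a per-sample ``sample_cohorts`` vector).
    stage
        One of :data:`STAGES`.
    sample_cohorts
        Optional per-sample cohort labels (index = sample IDs); set by
        :func:`stmir.datafusion.integrate_cohorts`.
    """

    values: pd.DataFrame
    modality: str
    cohort: str
    stage: str
    sample_cohorts: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate sample_ids: {list(dups[:5])}")
        if self.stage == "percentile":
            v = self.values.to_numpy()
            if v.size and (v.min() <= 0.0 or v.max() >= 1.0):
                raise ValueError("percentile stage requires values in (0,1)")
        if self.stage == "scaled01":
            v = self.values.to_numpy()
            if v.size and (v.min() < 0.0 or v.max() > 1.0):
                raise ValueError("scaled01 stage requires values in [0,1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExprMatrix":
        """Return a copy carrying new values and stage, same provenance."""
        return ExprMatrix(
            values=values,
            modality=self.modality,
            cohort=self.cohort,
            stage=stage,
            sample_cohorts=self.sample_cohorts,
        )


@dataclass
class IntegratedTrainingSet:
    """Aligned sample x gene features and sample x miRNA targets in [0, 1]."""

    X: pd.DataFrame
    Y: pd.DataFrame
    x_scaler: pd.DataFrame  # per-gene min/max used for the final scaling
    y_scaler: pd.DataFrame
    cohort_of_sample: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.Y.index):
            raise ValueError("X and Y rows must be aligned on identical sample_ids")

    @property
    def feature_genes(self) -> list:
        return list(self.X.columns)

    @property
    def target_mirnas(self) -> list:
        return list(self.Y.columns)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class SpotDataset:
    """Spot x gene counts with barcodes and array coordinates."""

    counts: np.ndarray  # spot x gene, non-negative
    barcodes: pd.Index
    gene_ids: pd.Index
    coords: Optional[np.ndarray] = None  # spot x 2 (col, row)

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.counts.shape != (len(self.barcodes), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )
        if self.barcodes.duplicated().any():
            raise ValueError("duplicate barcodes")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.coords is not None and len(self.coords) != len(self.barcodes):
            raise ValueError("coords must cover every spot")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def total_counts(self) -> np.ndarray:
        """Per-spot total counts."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def genes_detected(self) -> np.ndarray:
        """Per-spot number of genes with a non-zero count."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()


@dataclass
class ActivityMatrix:
    """Spot x miRNA predicted activity, each value in [0, 1]."""

    values: pd.DataFrame  # index = barcodes, columns = miRNA ids
    model_id: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("activity values must lie in [0,1]")

    @property
    def barcodes(self) -> pd.Index:
        return self.values.index

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.columns
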