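"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generators produce paired bulk cohorts with monotone batch distortions,
nonlinear miRNA-mRNA dependencies, and Visium-like spot mixtures with known
cell-type composition and latent activity.

Note the causal direction is deliberately inverted relative to biology:
synthetic miRNA "expression" is generated *as a function of* the mRNA
matrix, because that is exactly the prediction task the model poses.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import ExprMatrix, SpotDataset

FORMS = ("linear", "threshold", "product")

DistortionSpec = Union[None, str, Callable[[np.ndarray, np.random.Generator], np.ndarray]]


@dataclass
class MirnaRule:
    """One miRNA's generative dependence on its target genes."""

    name: str
    targets: np.ndarray  # gene indices
    weights: np.ndarray  # positive strengths
    signs: np.ndarray  # +-1 per target
    form: str  # linear | threshold | product
    thresholds: np.ndarray  # per-target cut points (threshold form only)


@dataclass
class RegulatoryTruth:
    """Ground truth shared by the bulk and spatial generators."""

    gene_names: List[str]
    mirna_names: List[str]
    gene_log_mean: np.ndarray
    gene_log_sd: np.ndarray
    rules: List[MirnaRule]
    celltype_names: List[str]
    celltype_z: np.ndarray  # celltype x gene latent profiles
    seed: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_names)

    @property
    def n_celltypes(self) -> int:
        return len(self.celltype_names)

    def nonlinear_mirnas(self) -> List[str]:
        return [r.name for r in self.rules if r.form != "linear"]

    def activity(self, Z: np.ndarray) -> np.ndarray:
        """Latent activity (n_mirnas x n_obs) from gene z-scores (genes x obs).

        Each rule's raw signal is standardized across the observations so
        a given noise_sd means the same signal-to-noise for every form.
        """
        n_obs = Z.shape[1]
        out = np.zeros((self.n_mirnas, n_obs))
        for i, rule in enumerate(self.rules):
            z = Z[rule.targets]
            sw = rule.signs * rule.weights
            if rule.form == "linear":
                raw = sw @ z
            elif rule.form == "threshold":
                raw = sw @ (z > rule.thresholds[:, None]).astype(float)
            elif rule.form == "product":
                half = len(rule.targets) // 2
                raw = np.zeros(n_obs)
                for a in range(half):
                    raw += sw[a] * z[2 * a] * z[2 * a + 1]
            else:  # pragma: no cover
                raise ValueError(rule.form)
            sd = raw.std()
            out[i] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
        return out


def make_truth(
    n_genes: int = 300,
    n_mirnas: int = 30,
    n_celltypes: int = 5,
    threshold_frac: float = 0.2,
    product_frac: float = 0.1,
    seed: int = 0,
) -> RegulatoryTruth:
    """Draw a regulatory ground truth; 20% threshold / 10% product forms by default."""
    if n_mirnas > n_genes:
        raise ValueError("n_mirnas must not exceed n_genes")
    if n_celltypes < 1:
        raise ValueError("need at least one cell type")
    rng = np.random.default_rng([seed, 101])
    gene_names = [f"gene{i:04d}" for i in range(n_genes)]
    mirna_names = [f"hsa-mir-{i:04d}" for i in range(n_mirnas)]
    gene_log_mean = rng.normal(2.0, 1.0, size=n_genes)
    gene_log_sd = rng.uniform(0.5, 1.5, size=n_genes)

    n_thr = int(round(threshold_frac * n_mirnas))
    n_prod = int(round(product_frac * n_mirnas))
    forms = ["threshold"] * n_thr + ["product"] * n_prod
    forms += ["linear"] * (n_mirnas - len(forms))

    rules = []
    for i, name in enumerate(mirna_names):
        k = int(rng.integers(4, 9))
        if forms[i] == "product":
            k += k % 2  # even number of targets for pairing
        targets = rng.choice(n_genes, size=k, replace=False)
        weights = rng.uniform(0.5, 1.5, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        thresholds = rng.normal(0.0, 0.5, size=k)
        rules.append(MirnaRule(name, targets, weights, signs, forms[i], thresholds))

    celltype_names = [f"celltype{i}" for i in range(n_celltypes)]
    celltype_z = rng.normal(0.0, 1.0, size=(n_celltypes, n_genes))
    return RegulatoryTruth(
        gene_names=gene_names,
        mirna_names=mirna_names,
        gene_log_mean=gene_log_mean,
        gene_log_sd=gene_log_sd,
        rules=rules,
        celltype_names=celltype_names,
        celltype_z=celltype_z,
        seed=seed,
    )


def apply_batch_distortion(
    raw: np.ndarray, spec: DistortionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Apply a strictly increasing per-sample map to each column of ``raw``."""
    if spec is None:
        return raw
    if callable(spec):
        return spec(raw, rng)
    n = raw.shape[1]
    if spec == "scale":
        factors = rng.uniform(2.0, 20.0, size=n)
        return raw * factors[None, :]
    if spec == "power":
        gammas = rng.uniform(0.5, 2.0, size=n)
        return raw ** gammas[None, :]
    if spec == "scale-power":
        factors = rng.uniform(2.0, 20.0, size=n)
        gammas = rng.uniform(0.5, 2.0, size=n)
        return (raw * factors[None, :]) ** gammas[None, :]
    raise ValueError(f"unknown batch distortion {spec!r}")


def generate_bulk_cohort(
    n_samples: int = 500,
    n_genes: int = 300,
    n_mirnas: int = 30,
    noise_sd: float = 0.1,
    cohort_label: str = "cohortA",
    batch_distortion: DistortionSpec = None,
    seed: int = 0,
    truth: Optional[RegulatoryTruth] = None,
) -> Tuple[ExprMatrix, ExprMatrix, RegulatoryTruth]:
    """Generate one paired (mRNA, miRNA) bulk cohort at the raw stage.

    Gene expression is log-normal; each miRNA's value is its rule's
    standardized activity plus N(0, noise_sd), mapped to a positive scale.
    ``batch_distortion`` applies per-sample strictly monotone maps after
    generation, so a distorted and an undistorted cohort share the same
    underlying draws.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth is None:
        truth = make_truth(n_genes=n_genes, n_mirnas=n_mirnas, seed=seed)
    if truth.n_mirnas > truth.n_genes:
        raise ValueError("n_mirnas must not exceed n_genes")
    label_key = zlib.crc32(cohort_label.encode())  # stable across processes
    rng = np.random.default_rng([seed, 202, label_key])
    Z = rng.standard_normal((truth.n_genes, n_samples))
    log_expr = truth.gene_log_mean[:, None] + truth.gene_log_sd[:, None] * Z
    mrna_raw = np.exp(log_expr)
    act = truth.activity(Z)
    noise = rng.standard_normal((truth.n_mirnas, n_samples)) * noise_sd
    mirna_raw = np.exp(act + noise)

    drng = np.random.default_rng([seed, 303, label_key])
    mrna_raw = apply_batch_distortion(mrna_raw, batch_distortion, drng)
    mirna_raw = apply_batch_distortion(mirna_raw, batch_distortion, drng)

    samples = [f"{cohort_label}-s{i:04d}" for i in range(n_samples)]
    mrna = ExprMatrix(
        pd.DataFrame(mrna_raw, index=truth.gene_names, columns=samples),
        modality="mRNA",
        cohort=cohort_label,
        stage="raw",
    )
    mirna = ExprMatrix(
        pd.DataFrame(mirna_raw, index=truth.mirna_names, columns=samples),
        modality="miRNA",
        cohort=cohort_label,
        stage="raw",
    )
    return mrna, mirna, truth


class SpatialTruthBundle(NamedTuple):
    spots: SpotDataset
    abundance: pd.DataFrame  # spot x celltype, arbitrary positive scale
    true_activity: pd.DataFrame  # spot x miRNA latent activity (z scale)
    proportions: pd.DataFrame  # spot x celltype, rows sum to 1
    planted_type: pd.Series  # dominant type per spot, or None


def generate_spatial_tissue(
    truth: RegulatoryTruth,
    n_spots: int = 200,
    dominant_fraction: float = 0.7,
    purity_range: Tuple[float, float] = (0.5, 0.95),
    depth_mean: float = 20000.0,
    seed: int = 0,
) -> SpatialTruthBundle:
    """Poisson spot counts from convex mixtures of cell-type profiles.

    A ``dominant_fraction`` of spots receive a planted dominant type with
    purity drawn from ``purity_range``; the rest are symmetric Dirichlet
    mixtures. True latent activity is the truth's functional forms applied
    to per-gene standardized log expected expression across spots.
    """
    if truth.n_celltypes == 0:
        raise ValueError("truth has zero cell types")
    lo, hi = purity_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("purity_range must lie within (0, 1]")
    rng = np.random.default_rng([seed, 404])
    n_ct = truth.n_celltypes
    profiles = np.exp(
        truth.gene_log_mean[None, :] + truth.gene_log_sd[None, :] * truth.celltype_z
    )  # celltype x gene

    props = np.empty((n_spots, n_ct))
    planted: List[Optional[str]] = []
    n_dom = int(round(dominant_fraction * n_spots))
    for s in range(n_spots):
        if s < n_dom:
            t = int(rng.integers(n_ct))
            p = float(rng.uniform(lo, hi))
            row = np.zeros(n_ct)
            if n_ct > 1:
                rest = rng.dirichlet(np.ones(n_ct - 1)) * (1 - p)
                row[np.arange(n_ct) != t] = rest
            row[t] = p if n_ct > 1 else 1.0
            planted.append(truth.celltype_names[t])
        else:
            row = rng.dirichlet(np.ones(n_ct))
            planted.append(None)
        props[s] = row

    mixed = props @ profiles  # spot x gene expected expression
    rel = mixed / mixed.sum(axis=1, keepdims=True)
    counts = rng.poisson(depth_mean * rel).astype(np.int64)

    logmix = np.log(mixed)
    mu = logmix.mean(axis=0)
    sd = logmix.std(axis=0)
    Zst = ((logmix - mu) / np.where(sd > 0, sd, 1.0)).T  # gene x spot
    act = truth.activity(Zst).T  # spot x miRNA

    barcodes = [f"spot-{s:04d}" for s in range(n_spots)]
    side = int(np.ceil(np.sqrt(n_spots)))
    coords = np.array([(s % side, s // side) for s in range(n_spots)], dtype=float)
    spots = SpotDataset(
        counts=counts,
        barcodes=pd.Index(barcodes),
        gene_ids=pd.Index(truth.gene_names),
        coords=coords,
    )
    scale = rng.uniform(0.5, 2.0, size=n_spots)  # exercise row normalization
    abundance = pd.DataFrame(
        props * scale[:, None], index=barcodes, columns=truth.celltype_names
    )
    return SpatialTruthBundle(
        spots=spots,
        abundance=abundance,
        true_activity=pd.DataFrame(act, index=barcodes, columns=truth.mirna_names),
        proportions=pd.DataFrame(props, index=barcodes, columns=truth.celltype_names),
        planted_type=pd.Series(planted, index=barcodes, dtype=object),
    )


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the complete small-file input surface of the CLI.

    Emits two paired cohort TSVs (one batch-distorted), an MTX Visium
    fixture with positions, an abundance CSV, a miRNA-target pair list and
    a three-set GMT. Regeneration with the same seed is byte-identical.
    Returns a dict of the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_truth(n_genes=60, n_mirnas=8, n_celltypes=3, seed=seed)
    mrna_a, mirna_a, _ = generate_bulk_cohort(
        n_samples=40, noise_sd=0.1, cohort_label="cohortA", seed=seed, truth=truth
    )
    mrna_b, mirna_b, _ = generate_bulk_cohort(
        n_samples=30,
        noise_sd=0.1,
        cohort_label="cohortB",
        batch_distortion="scale",
        seed=seed,
        truth=truth,
    )
    paths = {}
    for key, m in (
        ("cohortA_mrna", mrna_a),
        ("cohortA_mirna", mirna_a),
        ("cohortB_mrna", mrna_b),
        ("cohortB_mirna", mirna_b),
    ):
        p = out / f"{key}.tsv"
        m.values.to_csv(p, sep="\t", float_format="%.6g")
        paths[key] = p

    tissue = generate_spatial_tissue(
        truth, n_spots=49, dominant_fraction=0.8, purity_range=(0.6, 0.95),
        depth_mean=5000, seed=seed,
    )
    vdir = out / "visium"
    vdir.mkdir(exist_ok=True)
    coo = sparse.coo_matrix(tissue.spots.counts.T)  # gene x barcode on disk
    spio.mmwrite(str(vdir / "matrix.mtx"), coo, field="integer")
    (vdir / "barcodes.tsv").write_text("\n".join(tissue.spots.barcodes) + "\n")
    (vdir / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in tissue.spots.gene_ids)
    )
    pos_lines = [
        f"{b},1,{int(r)},{int(c)},{int(c)},{int(r)}"
        for b, (c, r) in zip(tissue.spots.barcodes, tissue.spots.coords)
    ]
    (out / "positions.csv").write_text("\n".join(pos_lines) + "\n")
    paths["visium"] = vdir
    paths["positions"] = out / "positions.csv"

    tissue.abundance.to_csv(out / "abundance.csv", float_format="%.6g")
    paths["abundance"] = out / "abundance.csv"

    pair_lines = [
        f"{rule.name}\t{truth.gene_names[t]}"
        for rule in truth.rules
        for t in rule.targets
    ]
    (out / "pairs.tsv").write_text("\n".join(pair_lines) + "\n")
    paths["pairs"] = out / "pairs.tsv"

    genes = truth.gene_names
    gmt_lines = [
        "setA\tsynthetic\t" + "\t".join(genes[0:15]),
        "setB\tsynthetic\t" + "\t".join(genes[10:30]),
        "setC\tsynthetic\t" + "\t".join(genes[30:50]),
    ]
    (out / "genesets.gmt").write_text("\n".join(gmt_lines) + "\n")
    paths["genesets"] = out / "genesets.gmt"
    return paths
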