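"""SNP filtering, mean imputation, LD pruning and the additive relationship matrix.

The marker pipeline for a panel of inbred accessions: heterozygous calls are
treated as likely genotyping errors, markers are screened on missingness and
minor allele frequency before and after mean imputation, near-duplicate markers
are removed by windowed r^2 pruning, and the surviving dosages feed VanRaden's
method-1 genomic relationship matrix G.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "filter_snps",
    "compute_grm",
    "read_dosage_csv",
    "read_vcf",
    "write_dosage_csv",
]


@dataclass
class GenotypeMatrix:
    """N x M biallelic dosage matrix with marker coordinates.

    ``dosages`` holds minor/alt-allele counts in [0, 2]; integers (with NaN for
    missing) before imputation, reals after. ``markers`` is a list of
    (chromosome, position) pairs aligned with the columns.
    """

    dosages: np.ndarray
    genotype_ids: list[str]
    markers: list[tuple[str, int]]
    imputed: bool = False  # True once missing calls have been replaced by column means

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        n, m = self.dosages.shape
        if len(self.genotype_ids) != n:
            raise ValueError("genotype_ids length mismatch")
        if len(self.markers) != m:
            raise ValueError("markers length mismatch")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("genotype ids must be unique")
        if any(pos < 0 for _, pos in self.markers):
            raise ValueError("marker positions must be non-negative")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def marker_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in self.markers]


@dataclass
class RelationshipMatrix:
    """Symmetric PSD N x N additive (genomic) relationship matrix G."""

    values: np.ndarray
    genotype_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise ValueError("shape does not match genotype_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8:
            raise ValueError(f"relationship matrix not PSD (min eigenvalue {w.min():.3g})")
        if np.any(np.diag(self.values) < -1e-12):
            raise ValueError("relationship matrix diagonal must be non-negative")

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        idx = [self.genotype_ids.index(i) for i in ids]
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.genotype_ids)


def _maf(col: np.ndarray) -> float:
    """Minor allele frequency of one dosage column, ignoring NaN."""
    p = np.nanmean(col) / 2.0
    return min(p, 1.0 - p)


def filter_snps(
    raw: GenotypeMatrix,
    het_call_policy: str = "drop_marker",
    missing_max: float = 0.95,
    maf1: float = 0.025,
    maf2: float = 0.05,
    ld_window: int = 25_000,
    ld_max: float = 0.8,
) -> GenotypeMatrix:
    """Apply the marker quality pipeline in its fixed order.

    1. heterozygous calls: ``drop_marker`` removes any marker with a het call
       (inbred panel; hets are treated as errors), ``mask`` sets them missing;
    2. drop markers with missing fraction > ``missing_max``;
    3. drop markers with MAF < ``maf1``;
    4. impute missing calls to the marker mean dosage;
    5. drop markers with MAF < ``maf2`` (recomputed after imputation);
    6. windowed LD pruning: for same-chromosome pairs closer than ``ld_window``
       bp with dosage r^2 >= ``ld_max``, greedily keep the left-most marker.

    MAF thresholds are strict (< keeps a marker sitting exactly on the bound).
    """
    if het_call_policy not in ("drop_marker", "mask"):
        raise ValueError("het_call_policy must be 'drop_marker' or 'mask'")
    for name, v in [("missing_max", missing_max), ("maf1", maf1), ("maf2", maf2), ("ld_max", ld_max)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    X = raw.dosages.copy()
    markers = list(raw.markers)

    # steps 1-2 interpret raw integer calls; a matrix that has already been
    # mean-imputed has no calls left to screen (keeps filtering idempotent)
    if not raw.imputed:
        het = X == 1
        if het_call_policy == "drop_marker":
            keep = ~het.any(axis=0)
            X, markers = X[:, keep], [m for m, k in zip(markers, keep) if k]
        else:
            X[het] = np.nan

        if X.shape[1]:
            miss_frac = np.isnan(X).mean(axis=0)
            keep = miss_frac <= missing_max
            X, markers = X[:, keep], [m for m, k in zip(markers, keep) if k]

    # 3. MAF pre-imputation
    if X.shape[1]:
        with np.errstate(invalid="ignore"):
            mafs = np.array([_maf(X[:, j]) for j in range(X.shape[1])])
        keep = mafs >= maf1
        X, markers = X[:, keep], [m for m, k in zip(markers, keep) if k]

    # 4. mean imputation
    if X.shape[1]:
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]

    # 5. MAF post-imputation
    if X.shape[1]:
        mafs = np.array([_maf(X[:, j]) for j in range(X.shape[1])])
        keep = mafs >= maf2
        X, markers = X[:, keep], [m for m, k in zip(markers, keep) if k]

    # 6. LD pruning, left-most marker wins ties
    if X.shape[1]:
        order = np.lexsort(([p for _, p in markers], [c for c, _ in markers]))
        kept: list[int] = []
        for j in order:
            chrom_j, pos_j = markers[j]
            ok = True
            for i in kept:
                chrom_i, pos_i = markers[i]
                if chrom_i != chrom_j or abs(pos_j - pos_i) >= ld_window:
                    continue
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                if np.isfinite(r) and r * r >= ld_max:
                    ok = False
                    break
            if ok:
                kept.append(j)
        kept_sorted = sorted(kept)
        X, markers = X[:, kept_sorted], [markers[i] for i in kept_sorted]

    if X.shape[1] == 0:
        raise ValueError("no markers survive filtering")
    return GenotypeMatrix(dosages=X, genotype_ids=list(raw.genotype_ids), markers=markers,
                          imputed=True)


def compute_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Markers are centred by twice their allele frequency (p_hat = mean dosage / 2)
    and G = W W' / (2 * sum p_hat (1 - p_hat)). Under Hardy-Weinberg genotypes
    the diagonal averages ~1, matching the pedigree-matrix scale.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("dosages contain missing values; impute first")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    # numerical PSD guard: clip tiny negative eigenvalues
    w, V = np.linalg.eigh(G)
    if w.min() < -1e-8:
        G = (V * np.clip(w, 0.0, None)) @ V.T
        G = (G + G.T) / 2.0
    return RelationshipMatrix(values=G, genotype_ids=list(geno.genotype_ids))


# ---------------------------------------------------------------------------
# readers / writers


def write_dosage_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Rows = genotypes, columns = 'chr:pos' marker ids."""
    pd.DataFrame(geno.dosages, index=geno.genotype_ids, columns=geno.marker_ids()).to_csv(
        path, index_label="genotype"
    )


def read_dosage_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    markers = []
    for col in df.columns:
        chrom, _, pos = str(col).rpartition(":")
        markers.append((chrom or str(col), int(pos) if pos.isdigit() else 0))
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        genotype_ids=[str(i) for i in df.index],
        markers=markers,
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Biallelic sites from a VCF; GT field converted to alt-dosage (NaN if any allele missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    markers: list[tuple[str, int]] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        gt = np.asarray(variant.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        cols.append(gt.sum(axis=1))
        markers.append((variant.CHROM, variant.POS))
    if not markers:
        raise ValueError("no biallelic sites in VCF")
    return GenotypeMatrix(dosages=np.column_stack(cols), genotype_ids=ids, markers=markers)
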