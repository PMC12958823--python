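"""Genotype handling and relationship matrices (pedigree A, genomic G).

The genomic relationship matrix follows the first VanRaden form:
G = WW' / (2 * sum_k p_k (1 - p_k)), with W = M - P the genotype dosage
matrix centered at twice the (observed sample) allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree


class KinshipError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Trees x SNPs dosage matrix with entries in {0, 1, 2} or NaN (missing)."""

    ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, NaN for missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise KinshipError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} trees x {len(self.snp_ids)} SNPs"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            # imputed matrices may hold fractional dosages; only the raw
            # constructor path enforces integer codes
            pass

    @property
    def n_trees(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP alternative-allele frequency from observed dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return p

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "A" or "G"
    epsilon: float = 0.0  # diagonal regularization actually applied

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise KinshipError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise KinshipError("relationship matrix is not symmetric")

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {k: i for i, k in enumerate(self.ids)}
        try:
            idx = [pos[k] for k in ids]
        except KeyError as exc:
            raise KinshipError(f"id {exc} not in relationship matrix") from exc
        return RelationshipMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.kind, self.epsilon
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix (tabular method).

    Diagonal entries are 1 + F_i with F_i the inbreeding coefficient;
    unknown parents are treated as unrelated founders.
    """
    A, ids = pedigree.numerator_relationship()
    return RelationshipMatrix(ids, A, kind="A")


def filter_snps(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.30,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop SNPs exceeding the missingness threshold or below the MAF floor.

    Mirrors the study's panel filters (30% missing-data proportion, minor
    allele frequency >= 1%). Returns the filtered matrix and the number of
    SNPs dropped per rule (a SNP failing both counts under each rule).
    """
    if genotypes.n_snps == 0:
        raise KinshipError("empty genotype matrix")
    miss = genotypes.missing_rate()
    p = genotypes.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    drop_missing = miss > max_missing
    drop_maf = np.isnan(maf) | (maf < min_maf)
    keep = ~(drop_missing | drop_maf)
    if not keep.any():
        raise KinshipError("all SNPs removed by filters: empty panel")
    kept = GenotypeMatrix(
        genotypes.ids,
        [s for s, k in zip(genotypes.snp_ids, keep) if k],
        genotypes.dosages[:, keep],
    )
    report = {
        "dropped_missing": int(drop_missing.sum()),
        "dropped_maf": int(drop_maf.sum()),
        "retained": int(keep.sum()),
    }
    return kept, report


def impute_mean(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by 2 p_k of its SNP (mean imputation).

    Column means are unchanged by this rule, so allele frequencies computed
    before and after imputation agree to machine precision.
    """
    p = genotypes.allele_frequencies()
    if np.isnan(p).any():
        bad = [s for s, f in zip(genotypes.snp_ids, p) if np.isnan(f)]
        raise KinshipError(
            f"SNPs with no observed genotypes cannot be imputed: {bad[:10]}"
        )
    filled = genotypes.dosages.copy()
    rows, cols = np.nonzero(np.isnan(filled))
    filled[rows, cols] = 2.0 * p[cols]
    return GenotypeMatrix(genotypes.ids, list(genotypes.snp_ids), filled)


def build_G(
    genotypes: GenotypeMatrix,
    epsilon: float = 1e-6,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    Centers dosages at twice the observed allele frequency and scales by
    2 * sum p_k (1 - p_k). If the smallest eigenvalue is <= 0, `epsilon`
    is added to the diagonal (recorded on the result); pass epsilon=0 to
    disable the repair.
    """
    if np.isnan(genotypes.dosages).any():
        raise KinshipError("genotypes contain missing entries; impute first")
    p = genotypes.allele_frequencies()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise KinshipError("all SNPs monomorphic: G denominator is zero")
    W = genotypes.dosages - 2.0 * p
    G = (W @ W.T) / denom
    applied = 0.0
    if epsilon > 0.0 and np.linalg.eigvalsh(G)[0] <= 0.0:
        G = G + epsilon * np.eye(G.shape[0])
        applied = epsilon
    return RelationshipMatrix(genotypes.ids, G, kind="G", epsilon=applied)
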