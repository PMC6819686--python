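"""Genomic relationship machinery: genotype QC, VanRaden G, blending, H-inverse.

The single-step H matrix never needs to be formed; its inverse is the sparse
pedigree A-inverse plus a dense correction on the genotyped block,

    H^-1 = A^-1 + [0 0; 0  tau * G_b^-1 - omega * A22^-1],

where G_b = alpha * G + beta * A22 is the blended genomic matrix.  tau scales
the genomic relationships and omega the pedigree relationships of the
genotyped animals; omega can be read as the share of polygenic variance the
markers leave unexplained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

logger = logging.getLogger(__name__)


class GenotypeError(ValueError):
    """Raised for degenerate or malformed genotype panels."""


@dataclass
class QCThresholds:
    """Marker/animal quality-control thresholds.

    Defaults are the conventional SNP-chip values: markers dropped when
    MAF < 0.01, marker call rate < 0.90 (missingness > 0.10), or the
    Hardy-Weinberg chi-square p-value < 1e-6; animals dropped when their
    call rate < 0.90.  Every rule can be disabled by setting it to None.
    """

    min_maf: float | None = 0.01
    max_marker_missing: float | None = 0.10
    max_animal_missing: float | None = 0.10
    hwe_alpha: float | None = 1e-6
    drop_monomorphic: bool = True
    drop_nonautosomal: bool = True

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_marker_missing", "max_animal_missing"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Counts removed per rule, in application order."""

    animals_removed: dict = field(default_factory=dict)
    markers_removed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("animal_missingness", 0, self.animals_removed.get("missingness", 0))]
        for rule in ("nonautosomal", "monomorphic", "missingness", "maf", "hwe"):
            rows.append((rule, self.markers_removed.get(rule, 0), 0))
        return pd.DataFrame(rows, columns=["rule", "markers_removed", "animals_removed"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Per-marker chi-square (1 df) Hardy-Weinberg test on genotype counts."""
    with np.errstate(invalid="ignore", divide="ignore"):
        n0 = np.nansum(dosages == 0, axis=0).astype(float)
        n1 = np.nansum(dosages == 1, axis=0).astype(float)
        n2 = np.nansum(dosages == 2, axis=0).astype(float)
        n = n0 + n1 + n2
        p = (2 * n2 + n1) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = np.zeros_like(p)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            ok = exp > 0
            chi2[ok] += (obs[ok] - exp[ok]) ** 2 / exp[ok]
        pv = stats.chi2.sf(chi2, df=1)
    pv[~np.isfinite(pv)] = 1.0
    # monomorphic markers are vacuously in HWE
    pv[(p <= 0) | (p >= 1)] = 1.0
    return pv


def qc_filter(
    dosages: np.ndarray,
    thresholds: QCThresholds | None = None,
    *,
    chromosomes: np.ndarray | None = None,
    autosomes: set | None = None,
):
    """Apply the QC chain: animals -> nonautosomal -> monomorphic -> missingness -> MAF -> HWE.

    Parameters
    ----------
    dosages : (n_animals, n_markers) float array with np.nan for missing.
    chromosomes : optional per-marker chromosome labels, used only by the
        nonautosomal rule (markers with non-integer labels, e.g. 'X', are dropped).

    Returns
    -------
    (filtered dosages, kept-animal index, kept-marker index, QCReport)
    """
    thresholds = thresholds or QCThresholds()
    X = np.asarray(dosages, dtype=float)
    n_animals, n_markers = X.shape
    report = QCReport()
    animal_keep = np.ones(n_animals, dtype=bool)
    marker_keep = np.ones(n_markers, dtype=bool)

    if thresholds.max_animal_missing is not None:
        miss = np.isnan(X).mean(axis=1)
        drop = miss > thresholds.max_animal_missing
        report.animals_removed["missingness"] = int(drop.sum())
        animal_keep &= ~drop
    Xa = X[animal_keep]

    if thresholds.drop_nonautosomal and chromosomes is not None:
        chroms = np.asarray(chromosomes)
        if autosomes is None:
            def is_autosome(c):
                try:
                    return int(c) >= 1
                except (TypeError, ValueError):
                    return False
            auto = np.array([is_autosome(c) for c in chroms])
        else:
            auto = np.isin(chroms, list(autosomes))
        report.markers_removed["nonautosomal"] = int((~auto & marker_keep).sum())
        marker_keep &= auto

    def _freq(cols):
        with np.errstate(invalid="ignore"):
            return np.nanmean(Xa[:, cols], axis=0) / 2.0

    if thresholds.drop_monomorphic:
        with np.errstate(invalid="ignore"):
            mono = np.zeros(n_markers, dtype=bool)
            live = np.where(marker_keep)[0]
            p = _freq(live)
            mono[live] = (p <= 0.0) | (p >= 1.0) | np.isnan(p)
        report.markers_removed["monomorphic"] = int(mono.sum())
        marker_keep &= ~mono

    if thresholds.max_marker_missing is not None:
        miss = np.isnan(Xa).mean(axis=0)
        drop = (miss > thresholds.max_marker_missing) & marker_keep
        report.markers_removed["missingness"] = int(drop.sum())
        marker_keep &= ~drop

    if thresholds.min_maf is not None:
        live = np.where(marker_keep)[0]
        p = _freq(live)
        maf = np.minimum(p, 1.0 - p)
        drop = np.zeros(n_markers, dtype=bool)
        drop[live] = maf < thresholds.min_maf
        report.markers_removed["maf"] = int(drop.sum())
        marker_keep &= ~drop

    if thresholds.hwe_alpha is not None:
        live = np.where(marker_keep)[0]
        pv = hwe_pvalues(Xa[:, live])
        drop = np.zeros(n_markers, dtype=bool)
        drop[live] = pv < thresholds.hwe_alpha
        report.markers_removed["hwe"] = int(drop.sum())
        marker_keep &= ~drop

    if not marker_keep.any():
        raise GenotypeError("QC removed every marker; panel is empty")
    return (
        X[np.ix_(animal_keep, marker_keep)],
        np.where(animal_keep)[0],
        np.where(marker_keep)[0],
        report,
    )


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-marker allele frequency p = mean dosage / 2 over non-missing entries."""
    X = np.asarray(dosages, dtype=float)
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs == 0).any():
        raise GenotypeError("marker with all dosages missing; run QC first")
    with np.errstate(invalid="ignore"):
        return np.nanmean(X, axis=0) / 2.0


def impute_mean(dosages: np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """Fill missing dosages with 2 p_m (the mean dosage)."""
    X = np.array(dosages, dtype=float, copy=True)
    if freqs is None:
        freqs = allele_frequencies(X)
    miss = np.isnan(X)
    X[miss] = np.broadcast_to(2.0 * freqs, X.shape)[miss]
    return X


def build_G(dosages: np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    Z = M - 2p (columns centered at twice the allele frequency);
    G = Z Z' / (2 sum_m p_m (1 - p_m)).
    """
    X = np.asarray(dosages, dtype=float)
    if np.isnan(X).any():
        raise GenotypeError("missing dosages; impute (impute_mean) before build_G")
    if freqs is None:
        freqs = allele_frequencies(X)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise GenotypeError("sum 2p(1-p) is zero: no polymorphic markers")
    Z = X - 2.0 * freqs
    return (Z @ Z.T) / denom


def blend_G(G: np.ndarray, A22: np.ndarray, alpha: float = 0.95, beta: float = 0.05) -> np.ndarray:
    """G_b = alpha G + beta A22; the small pedigree share keeps G_b invertible."""
    G = np.asarray(G)
    A22 = np.asarray(A22)
    if G.shape != A22.shape:
        raise ValueError(f"shape mismatch: G {G.shape} vs A22 {A22.shape}")
    if not np.isclose(alpha + beta, 1.0):
        raise ValueError(f"blend weights must sum to 1, got {alpha}+{beta}")
    return alpha * G + beta * A22


@dataclass
class RelationshipSet:
    """Bundle of relationship matrices and tuning metadata for one model."""

    G: np.ndarray
    A22: np.ndarray
    G_b: np.ndarray
    tau: float
    omega: float
    alpha_blend: float
    beta_blend: float
    genotyped_ids: np.ndarray
    H_inv: sp.csr_matrix | None = None
    logdet_H: float | None = None


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    G_b: np.ndarray,
    tau: float,
    omega: float,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """Assemble sparse H-inverse with the tau/omega-tuned genotyped block.

    genotyped_index gives the 0-based pedigree row of each genotyped animal,
    in the row order of G_b / A22.
    """
    gix = np.asarray(genotyped_index, dtype=np.int64)
    n = A_inv.shape[0]
    if len(gix) == 0:
        return sp.csr_matrix(A_inv)
    for name, M in (("G_b", G_b), ("A22", A22)):
        cond = np.linalg.cond(M)
        logger.info("condition number of %s: %.3e", name, cond)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"{name} is (near-)singular (cond={cond:.2e}); consider blending "
                "more pedigree (larger beta) or adjusting omega"
            )
    block = tau * np.linalg.inv(G_b) - omega * np.linalg.inv(A22)
    rows = np.repeat(gix, len(gix))
    cols = np.tile(gix, len(gix))
    H_inv = sp.csr_matrix(A_inv) + sp.csr_matrix(
        (block.ravel(), (rows, cols)), shape=(n, n)
    )
    return H_inv


def assemble_relationships(
    pedigree,
    genotypes,
    thresholds: QCThresholds | None = None,
    tau: float = 1.0,
    omega: float = 1.0,
    alpha_blend: float = 0.95,
    chromosomes: np.ndarray | None = None,
) -> RelationshipSet:
    """Full chain: QC -> allele frequencies -> G -> A22 -> blend -> H-inverse.

    genotypes is an animals x markers DataFrame (index = animal ids, dosage
    values with NaN for missing).  Returns a populated RelationshipSet.
    """
    from .pedigree import build_A22, build_A_inverse

    dosages, animal_keep, _, _ = qc_filter(
        genotypes.to_numpy(dtype=float), thresholds, chromosomes=chromosomes
    )
    ids = genotypes.index.to_numpy()[animal_keep]
    freqs = allele_frequencies(dosages)
    G = build_G(impute_mean(dosages, freqs), freqs)
    A22 = build_A22(pedigree, ids)
    G_b = blend_G(G, A22, alpha_blend, 1.0 - alpha_blend)
    H_inv = build_H_inverse(
        build_A_inverse(pedigree), A22, G_b, tau, omega, pedigree.indices_of(ids)
    )
    return RelationshipSet(
        G=G, A22=A22, G_b=G_b, tau=tau, omega=omega,
        alpha_blend=alpha_blend, beta_blend=1.0 - alpha_blend,
        genotyped_ids=ids, H_inv=H_inv,
    )


def g_a22_offdiag_correlation(G: np.ndarray, A22: np.ndarray) -> float:
    """Pearson correlation of strictly-lower-triangle elements of G and A22."""
    G = np.asarray(G)
    A22 = np.asarray(A22)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 animals for an off-diagonal correlation")
    il = np.tril_indices_from(G, k=-1)
    g, a = G[il], A22[il]
    if np.std(a) == 0 or np.std(g) == 0:
        raise ValueError("off-diagonal elements constant; correlation undefined")
    return float(np.corrcoef(g, a)[0, 1])
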