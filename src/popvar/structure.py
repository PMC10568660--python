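"""Population structure: LD pruning of alt-allele dosages and sample PCA.

r-squared is computed on unphased dosages (Rogers-Huff style), not
haplotypes; RNA-seq genotypes are unphased and pooled samples cannot be
phased. Pruning iterates sliding windows to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, CalledVariants, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DosageMatrix:
    """Alt-allele dosage per site x sample, with positions and a pruned mask.

    Dosages are integral in [0, ploidy]; missing genotypes are NaN. ``kept``
    marks sites surviving LD pruning (all True before pruning).
    """

    dosage: np.ndarray  # (n_sites, n_samples) float, NaN = missing
    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    ploidy: int
    kept: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(len(self.pos), dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def dosage_matrix(v: CalledVariants) -> DosageMatrix:
    """Dosage of the most frequent alt allele per site (biallelic reduction)."""
    g = v.genotypes
    flat = g.reshape(v.n_sites, -1)
    max_allele = int(flat.max()) if flat.size else 0
    # most frequent alt allele index per site across all samples
    alt_counts = np.stack(
        [(flat == a).sum(axis=1) for a in range(1, max_allele + 1)], axis=1
    ) if max_allele >= 1 else np.zeros((v.n_sites, 1), dtype=int)
    top = alt_counts.argmax(axis=1) + 1
    dose = (g == top[:, None, None]).sum(axis=2).astype(float)
    dose[(g == MISSING).any(axis=2)] = np.nan
    return DosageMatrix(
        dosage=dose, chrom=v.chrom.copy(), pos=v.pos.copy(),
        samples=list(v.samples), ploidy=v.ploidy,
    )


def _imputed(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per site; all-missing sites become 0."""
    out = dosage.copy()
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.info("mean-imputing %d missing dosage value(s)", n_missing)
        means = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=1)
        means = np.nan_to_num(means, nan=0.0)
        idx = np.where(np.isnan(out))
        out[idx] = means[idx[0]]
    return out


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; NaN if either is constant."""
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    d: DosageMatrix,
    window_snps: int = 500,
    step_snps: int = 250,
    r2_threshold: float = 0.01,
) -> DosageMatrix:
    """Remove the later site of each pair with r^2 strictly above threshold.

    Sliding windows of ``window_snps`` kept sites advance by ``step_snps``;
    sweeps repeat until a full pass removes nothing, so the result is a
    fixed point (pruning it again removes nothing). Zero-variance sites
    cannot be scored and are retained (logged).
    """
    if d.n_sites < 2:
        raise ValidationError("LD pruning requires at least 2 sites")
    dose = _imputed(d.dosage)
    kept = d.kept.copy()
    n_const = int((np.std(dose, axis=1) == 0).sum())
    if n_const:
        logger.info("%d zero-variance site(s) cannot be pruned by r2; retained", n_const)
    changed = True
    while changed:
        changed = False
        kept_idx = np.flatnonzero(kept)
        for start in range(0, max(len(kept_idx), 1), step_snps):
            window = kept_idx[start:start + window_snps]
            window = window[kept[window]]  # may have been removed this pass
            for a in range(len(window)):
                i = window[a]
                if not kept[i]:
                    continue
                for b in range(a + 1, len(window)):
                    j = window[b]
                    if not kept[j]:
                        continue
                    r2 = pairwise_r2(dose[i], dose[j])
                    if not np.isnan(r2) and r2 > r2_threshold:
                        kept[j] = False
                        changed = True
            if start + window_snps >= len(kept_idx):
                break
    return DosageMatrix(
        dosage=d.dosage, chrom=d.chrom, pos=d.pos,
        samples=d.samples, ploidy=d.ploidy, kept=kept,
    )


@dataclass
class PCAResult:
    """Sample coordinates on k principal components with variance fractions."""

    coords: np.ndarray              # (n_samples, k)
    explained_variance_ratio: np.ndarray
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.insert(0, "sample", self.samples)
        return df


def pca(d: DosageMatrix, n_components: int = 2) -> PCAResult:
    """PCA of samples on site-centered dosages via SVD.

    Only sites marked kept (post-pruning) enter. Missing dosages are
    mean-imputed per site. The per-component sign is fixed by making the
    largest-magnitude site loading positive, so results are deterministic.
    """
    n_samples = len(d.samples)
    if n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if n_components > n_samples - 1:
        raise ValidationError(
            f"n_components={n_components} exceeds n_samples-1={n_samples - 1}"
        )
    dose = _imputed(d.dosage)[d.kept]
    x = dose.T - dose.mean(axis=1)  # (samples, sites), site-centered
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(len(s)):
        lead = np.argmax(np.abs(vt[k]))
        if vt[k, lead] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    total = (s**2).sum()
    evr = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    return PCAResult(coords=coords, explained_variance_ratio=evr,
                     samples=list(d.samples))
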