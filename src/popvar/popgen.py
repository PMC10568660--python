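"""Selection and diversity statistics on grouped allele counts.

Implements Hudson's two-population differentiation estimator from per-site
numerator/denominator components, windowed and per-gene ratio-of-averages
aggregation, the population branch statistic, nucleotide diversity, the
segregating-sites diversity estimator, and an observed/expected
heterozygosity inbreeding coefficient.

Negative per-site component ratios are deliberately kept in sums (not
truncated at zero) so windowed estimates stay unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    MISSING,
    AnalysisConfig,
    CalledVariants,
    GenomeAnnotation,
    GroupedAlleleCounts,
    SampleSheet,
    ValidationError,
    biallelic_pair,
    group_allele_counts,
)

logger = logging.getLogger(__name__)

PBS_CLIP_EPS = 1e-6


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

@dataclass
class HudsonComponents:
    """Per-site numerator/denominator components for a pair of groups.

    Sites where either group has fewer than 2 called haplotypes are masked
    (NaN in both components) and excluded from all aggregations.
    """

    chrom: np.ndarray
    pos: np.ndarray
    num: np.ndarray   # N-hat per site
    den: np.ndarray   # D-hat per site

    @property
    def mask(self) -> np.ndarray:
        """True where the site contributes (components defined)."""
        return ~np.isnan(self.den)

    def per_site_fst(self) -> np.ndarray:
        """Per-site ratio where the denominator is positive, else NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.den > 0, self.num / self.den, np.nan)


def hudson_fst_components(
    ac_a: np.ndarray,
    ac_b: np.ndarray,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> HudsonComponents:
    """Compute per-site Hudson estimator components from biallelic counts.

    ``ac_a``/``ac_b`` are (n_sites, 2) [ref, alt] count arrays. Per site,

        N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1)

    with p the alt-allele frequency and n the called haplotype count.
    """
    ac_a = np.asarray(ac_a, dtype=float)
    ac_b = np.asarray(ac_b, dtype=float)
    if ac_a.shape != ac_b.shape or ac_a.ndim != 2 or ac_a.shape[1] != 2:
        raise ValidationError("expected two (n_sites, 2) biallelic count arrays")
    n1 = ac_a.sum(axis=1)
    n2 = ac_b.sum(axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise ValidationError("insufficient haplotypes: no site has n >= 2 in both groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ac_a[:, 1] / n1
        p2 = ac_b[:, 1] / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    n_sites = len(num)
    if chrom is None:
        chrom = np.array(["0"] * n_sites, dtype=object)
    if pos is None:
        pos = np.arange(1, n_sites + 1, dtype=np.int64)
    return HudsonComponents(chrom=np.asarray(chrom, dtype=object),
                            pos=np.asarray(pos, dtype=np.int64),
                            num=num, den=den)


def hudson_fst_from_groups(
    gac: GroupedAlleleCounts, group_a: str, group_b: str
) -> HudsonComponents:
    """Hudson components for a named contrast, after biallelic reduction."""
    ac_a, ac_b = biallelic_pair(gac, group_a, group_b)
    return hudson_fst_components(ac_a, ac_b, chrom=gac.chrom, pos=gac.pos)


def genome_wide_fst(comp: HudsonComponents) -> float:
    """Ratio-of-averages estimate over all unmasked sites."""
    m = comp.mask
    den = np.nansum(comp.den[m])
    if den <= 0:
        return np.nan
    return float(np.nansum(comp.num[m]) / den)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def tile_windows(
    chrom_order: list[str],
    max_pos: dict[str, int],
    window_size_bp: int,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """1-based inclusive windows tiling each chromosome up to ``max_pos``.

    With ``step_bp`` unset, windows are nonoverlapping and tile without gaps.
    """
    step = step_bp or window_size_bp
    rows = []
    for c in chrom_order:
        start = 1
        while start <= max_pos[c]:
            rows.append((c, start, start + window_size_bp - 1))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _windows_for(comp_chrom, comp_pos, window_size_bp, step_bp=None) -> pd.DataFrame:
    chrom_order = list(dict.fromkeys(comp_chrom))
    max_pos = {c: int(comp_pos[comp_chrom == c].max()) for c in chrom_order}
    return tile_windows(chrom_order, max_pos, window_size_bp, step_bp)


def windowed_fst(
    comp: HudsonComponents,
    window_size_bp: int,
    step_bp: int | None = None,
    windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ratio-of-averages Hudson estimate per window.

    Returns columns chrom, start, end, fst, n_snps; ``fst`` is NaN where the
    summed denominator is zero (including empty windows).
    """
    if windows is None:
        windows = _windows_for(comp.chrom, comp.pos, window_size_bp, step_bp)
    vals = np.full(len(windows), np.nan)
    n_snps = np.zeros(len(windows), dtype=np.int64)
    m = comp.mask
    for i, (c, start, end) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        sel = m & (comp.chrom == c) & (comp.pos >= start) & (comp.pos <= end)
        n_snps[i] = int(sel.sum())
        if n_snps[i] == 0:
            continue
        den = comp.den[sel].sum()
        if den > 0:
            vals[i] = comp.num[sel].sum() / den
    out = windows.copy()
    out["fst"] = vals
    out["n_snps"] = n_snps
    return out


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

@dataclass
class PBSResult:
    """Branch lengths and PBS per window (or gene) for a focal group A."""

    table: pd.DataFrame  # chrom,start,end,t_ab,t_ac,t_bc,pbs,clipped


def _branch_length(fst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fst = np.asarray(fst, dtype=float)
    clipped = fst >= 1 - PBS_CLIP_EPS
    safe = np.clip(fst, None, 1 - PBS_CLIP_EPS)
    with np.errstate(invalid="ignore"):
        t = -np.log(1 - safe)
    return t, clipped


def pbs(
    fst_ab: pd.DataFrame, fst_ac: pd.DataFrame, fst_bc: pd.DataFrame
) -> PBSResult:
    """Population branch statistic for focal group A from three F_ST tables.

    Tables must be aligned on identical (chrom, start, end) windows.
    PBS = (T_AB + T_AC - T_BC) / 2 with T = -log(1 - F_ST), F_ST clipped
    to [., 1 - 1e-6]; rows where clipping engaged are flagged.
    """
    key = ["chrom", "start", "end"]
    for other in (fst_ac, fst_bc):
        if not fst_ab[key].reset_index(drop=True).equals(
            other[key].reset_index(drop=True)
        ):
            raise ValidationError("PBS inputs are not aligned on identical windows")
    t_ab, c1 = _branch_length(fst_ab["fst"].to_numpy())
    t_ac, c2 = _branch_length(fst_ac["fst"].to_numpy())
    t_bc, c3 = _branch_length(fst_bc["fst"].to_numpy())
    out = fst_ab[key].copy()
    out["t_ab"] = t_ab
    out["t_ac"] = t_ac
    out["t_bc"] = t_bc
    out["pbs"] = (t_ab + t_ac - t_bc) / 2.0
    out["clipped"] = c1 | c2 | c3
    return PBSResult(table=out)


def pbs_values(fst_ab, fst_ac, fst_bc):
    """Scalar/array convenience wrapper: PBS from raw F_ST values."""
    t_ab, _ = _branch_length(np.atleast_1d(fst_ab))
    t_ac, _ = _branch_length(np.atleast_1d(fst_ac))
    t_bc, _ = _branch_length(np.atleast_1d(fst_bc))
    out = (t_ab + t_ac - t_bc) / 2.0
    return float(out[0]) if out.size == 1 else out


# ---------------------------------------------------------------------------
# Diversity: pi, Watterson's theta, bootstrap CIs
# ---------------------------------------------------------------------------

def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (0 for k <= 0)."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k > 0 else 0.0


def site_pairwise_diversity(counts: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference: sum_{j<k} c_j c_k / C(n, 2).

    ``counts`` is (n_sites, n_alleles); sites with n < 2 return NaN.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    pairs_diff = (n**2 - (counts**2).sum(axis=1)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = n * (n - 1) / 2.0
        return np.where(n >= 2, pairs_diff / denom, np.nan)


def windowed_diversity(
    counts: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    window_size_bp: int,
    step_bp: int | None = None,
    windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Windowed pi and Watterson's theta per base pair.

    Per window: pi = sum of per-site pairwise diversity / window span;
    theta = sum over segregating sites of 1/a_{n_i - 1} / window span
    (reducing to S / (a_{n-1} * L) at constant n). The window span is the
    full window length; coverage gaps are not corrected for.
    """
    if windows is None:
        windows = _windows_for(chrom, pos, window_size_bp, step_bp)
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    site_pi = np.nan_to_num(site_pairwise_diversity(counts), nan=0.0)
    seg = (counts > 0).sum(axis=1) >= 2
    a_prev = np.array([harmonic_number(int(k) - 1) for k in n])
    with np.errstate(invalid="ignore", divide="ignore"):
        site_theta = np.where(seg & (a_prev > 0), 1.0 / np.where(a_prev > 0, a_prev, 1), 0.0)

    pis = np.zeros(len(windows))
    thetas = np.zeros(len(windows))
    svals = np.zeros(len(windows), dtype=np.int64)
    nvar = np.zeros(len(windows), dtype=np.int64)
    for i, (c, start, end) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        sel = (chrom == c) & (pos >= start) & (pos <= end)
        span = end - start + 1
        pis[i] = site_pi[sel].sum() / span
        thetas[i] = site_theta[sel].sum() / span
        svals[i] = int(seg[sel].sum())
        nvar[i] = int(sel.sum())
    out = windows.copy()
    out["pi"] = pis
    out["theta"] = thetas
    out["S"] = svals
    out["n_variants"] = nvar
    return out


def bootstrap_ci(
    values: np.ndarray, n_resamples: int, seed: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Mean with a seeded percentile-bootstrap CI over windows."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    mean = float(values.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return mean, float(lo), float(hi)


@dataclass
class DiversityResult:
    """Per-group windowed diversity plus genome-wide bootstrap summaries."""

    windows: dict[str, pd.DataFrame]
    summary: pd.DataFrame  # group, pi, pi_ci_low, pi_ci_high, theta, ...
    f_is: dict[str, float] = field(default_factory=dict)


def diversity(
    v: CalledVariants,
    sheet: SampleSheet,
    config: AnalysisConfig,
    n_downsample: int | None = None,
    n_bootstrap: int = 10_000,
    seed: int | None = None,
) -> DiversityResult:
    """Windowed pi/theta per group with genome-wide bootstrap 95% CIs.

    With ``n_downsample`` set, each group larger than that size is first
    down-sampled (seeded) to standardize sample sizes across groups.
    """
    seed = config.random_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    windows: dict[str, pd.DataFrame] = {}
    rows = []
    for group, sample_ids in sheet.groups.items():
        ids = list(sample_ids)
        if n_downsample is not None and len(ids) > n_downsample:
            ids = sorted(rng.choice(ids, size=n_downsample, replace=False).tolist())
            logger.info("group %s down-sampled to %d replicates", group, n_downsample)
        sub = v.take_samples(ids)
        if sub.n_samples * sub.ploidy < 2:
            raise ValidationError(f"group {group} has fewer than 2 haplotypes")
        gac = group_allele_counts(
            sub, SampleSheet(pd.DataFrame({"sampleID": ids, "treatment": group}))
        )
        wd = windowed_diversity(
            gac.counts[group], gac.chrom, gac.pos,
            config.window_size_bp, config.window_step_bp,
        )
        windows[group] = wd
        pi_m, pi_lo, pi_hi = bootstrap_ci(wd["pi"].to_numpy(), n_bootstrap, seed)
        th_m, th_lo, th_hi = bootstrap_ci(wd["theta"].to_numpy(), n_bootstrap, seed + 1)
        rows.append((group, pi_m, pi_lo, pi_hi, th_m, th_lo, th_hi))
    summary = pd.DataFrame(
        rows,
        columns=["group", "pi", "pi_ci_low", "pi_ci_high",
                 "theta", "theta_ci_low", "theta_ci_high"],
    )
    return DiversityResult(windows=windows, summary=summary)


# ---------------------------------------------------------------------------
# Inbreeding coefficient
# ---------------------------------------------------------------------------

def inbreeding_coefficient(v: CalledVariants, sheet: SampleSheet) -> dict[str, float]:
    """Per-group F_IS = 1 - mean(H_obs) / mean(H_exp) over polymorphic sites.

    H_obs is the fraction of fully-called samples that are heterozygous
    (any two haplotype calls differ); H_exp = 1 - sum_j p_j^2 from group
    allele frequencies. Sites with H_exp = 0 are excluded; a group with no
    polymorphic site yields NaN with a warning.
    """
    if v.ploidy < 2:
        raise ValidationError("inbreeding coefficient requires ploidy >= 2")
    out: dict[str, float] = {}
    for group, sample_ids in sheet.groups.items():
        idx = [v.samples.index(s) for s in sample_ids]
        g = v.genotypes[:, idx, :]  # (sites, samples, ploidy)
        called = ~(g == MISSING).any(axis=2)  # fully-called samples only
        het = (g.max(axis=2) != g.min(axis=2)) & called
        n_called = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_obs = np.where(n_called > 0, het.sum(axis=1) / n_called, np.nan)
        # allele frequencies from all non-missing haplotypes in the group
        flat = g.reshape(v.n_sites, -1)
        n_hap = (flat != MISSING).sum(axis=1).astype(float)
        max_allele = int(flat.max()) if flat.size else 0
        sum_p2 = np.zeros(v.n_sites)
        for a in range(max_allele + 1):
            with np.errstate(invalid="ignore", divide="ignore"):
                pa = np.where(n_hap > 0, (flat == a).sum(axis=1) / n_hap, 0.0)
            sum_p2 += pa**2
        h_exp = 1.0 - sum_p2
        usable = (h_exp > 0) & ~np.isnan(h_obs)
        if not usable.any():
            logger.warning("group %s: all sites monomorphic; F_IS undefined", group)
            out[group] = np.nan
            continue
        out[group] = float(1.0 - h_obs[usable].mean() / h_exp[usable].mean())
    return out


# ---------------------------------------------------------------------------
# Per-gene F_ST
# ---------------------------------------------------------------------------

def per_gene_fst(
    comp: HudsonComponents,
    annotation: GenomeAnnotation,
    fst_top_percentile: float = 5.0,
) -> pd.DataFrame:
    """Ratio-of-averages estimate per gene span, with percentile flags.

    Percentile rank (weak: 100 * #{genes with value <= this} / #ranked) is
    computed over genes with at least one contributing variant; a gene is
    flagged when rank > 100 - ``fst_top_percentile``, so with n distinct
    values exactly floor(n * pct / 100) genes are flagged. Genes without
    variants get NaN and no rank.
    """
    m = comp.mask
    rows = []
    for _, g in annotation.genes.iterrows():
        sel = m & (comp.chrom == g["chrom"]) & \
            (comp.pos >= g["start"]) & (comp.pos <= g["end"])
        n_var = int(sel.sum())
        val = np.nan
        if n_var > 0:
            den = comp.den[sel].sum()
            if den > 0:
                val = comp.num[sel].sum() / den
        rows.append((g["gene_id"], g["chrom"], int(g["start"]), int(g["end"]),
                     val, n_var))
    out = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "fst", "n_variants"]
    )
    ranked = out["fst"].notna()
    ranks = np.full(len(out), np.nan)
    if ranked.any():
        vals = out.loc[ranked, "fst"].to_numpy()
        ranks[ranked.to_numpy()] = [
            sps.percentileofscore(vals, x, kind="weak") for x in vals
        ]
    out["percentile_rank"] = ranks
    out["top_percentile"] = ranked.to_numpy() & (
        np.nan_to_num(ranks, nan=-1.0) > 100.0 - fst_top_percentile
    )
    return out
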