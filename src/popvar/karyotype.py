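"""Pooled-sample chromosomal inversion karyotyping from tag SNPs.

Per sample, the inversion frequency is the mean over covered tag SNPs of
the inverted-allele read fraction: 0 means no inverted alleles across tag
loci, 1 means all inverted alleles. Groups are compared with Mann-Whitney
U tests, BH-adjusted across contrasts x inversions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .allele_balance import BASES, PileupCounts
from .core_io import SampleSheet, TagSNPPanel

logger = logging.getLogger(__name__)


def karyotype_frequency(
    p: PileupCounts,
    panel: TagSNPPanel,
    samples: list[str] | None = None,
    depth_weighted: bool = False,
) -> pd.DataFrame:
    """Per-sample inverted-allele frequency for one inversion.

    The unweighted mean over covered tag SNPs of (inverted-allele reads /
    depth); ``depth_weighted=True`` pools reads across tags instead. A
    sample with zero covered tags gets NaN with a warning, not an error.
    Uncovered tags never affect the estimate.
    """
    samples = samples if samples is not None else p.samples
    rows = []
    for sample in samples:
        fracs = []
        inv_reads = depth_total = 0
        for tag in panel.tags:
            counts = p.counts_at(sample, panel.chrom, tag.pos)
            if counts is None:
                continue
            depth = sum(counts.values())
            if depth == 0:
                continue
            fracs.append(counts[tag.inverted_allele] / depth)
            inv_reads += counts[tag.inverted_allele]
            depth_total += depth
        if not fracs:
            logger.warning(
                "sample %s: no covered %s tag SNPs; frequency missing",
                sample, panel.inversion,
            )
            freq = np.nan
        elif depth_weighted:
            freq = inv_reads / depth_total
        else:
            freq = float(np.mean(fracs))
        rows.append((sample, panel.inversion, freq, len(panel.tags), len(fracs)))
    return pd.DataFrame(
        rows, columns=["sample", "inversion", "frequency", "n_tags", "n_covered"]
    )


def group_karyotype_summary(
    freqs: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """Mean frequency per treatment group per inversion."""
    df = freqs.copy()
    df["group"] = [sheet.group_of(s) for s in df["sample"]]
    out = (
        df.groupby(["group", "inversion"], sort=True)["frequency"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "frequency", "count": "n_replicates"})
    )
    return out


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not ties and max(len(x), len(y)) <= 8:
        method = "exact"
    else:
        method = "asymptotic"  # midranks + continuity correction
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def compare_karyotypes(
    freqs: pd.DataFrame,
    sheet: SampleSheet,
    contrasts: list[tuple[str, str]],
) -> pd.DataFrame:
    """Mann-Whitney U per contrast x inversion with BH adjustment.

    Exact two-sided p-values are used when both groups have <= 8 replicates
    and no ties; otherwise the normal approximation with midranks and
    continuity correction. Contrasts with fewer than 2 replicates in either
    group are skipped with a warning. The adjustment method (BH) is logged,
    as it is a documented choice.
    """
    df = freqs.copy()
    df["group"] = [sheet.group_of(s) for s in df["sample"]]
    rows = []
    for inversion, sub in df.groupby("inversion", sort=True):
        for ga, gb in contrasts:
            x = sub.loc[sub["group"] == ga, "frequency"].dropna().to_numpy()
            y = sub.loc[sub["group"] == gb, "frequency"].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                logger.warning(
                    "contrast %s vs %s on %s skipped: <2 replicates in a group",
                    ga, gb, inversion,
                )
                continue
            u, pval, method = _mwu(x, y)
            rows.append((inversion, ga, gb, len(x), len(y), u, pval, method))
    out = pd.DataFrame(
        rows,
        columns=["inversion", "group_a", "group_b", "n_a", "n_b",
                 "u_statistic", "p_value", "method"],
    )
    if len(out):
        out["p_adjusted"] = sps.false_discovery_control(
            out["p_value"].to_numpy(), method="bh"
        )
        logger.info("p-values adjusted with Benjamini-Hochberg across %d tests", len(out))
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
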