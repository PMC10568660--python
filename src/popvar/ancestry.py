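"""Ancestry fractions from ancestry-informative markers (AIMs).

AIMs are loci with (almost) fixed allele differences between two species.
Allele observations matching the species-A or species-B diagnostic allele
are tallied per chromosome; observations matching neither are counted as
uninformative and never assigned to either species. Heterozygous calls are
half-counted (one allele copy to each matching species). Pooled samples are
reported as fractions, not per-locus majority votes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allele_balance import BASES, PileupCounts
from .core_io import MISSING, AIMPanel, CalledVariants, SampleSheet, ValidationError


@dataclass
class AncestryResult:
    """Per-sample per-chromosome AIM tallies and aggregate fractions.

    ``per_chrom`` columns: sample, group, chrom, n_called, count_a, count_b,
    count_other, fraction_a. ``per_sample`` aggregates over chromosomes;
    ``per_group`` averages per-sample genome-wide fractions.
    """

    panel_label: str
    per_chrom: pd.DataFrame
    per_sample: pd.DataFrame
    per_group: pd.DataFrame


def aim_ancestry(
    source: CalledVariants | PileupCounts,
    panel: AIMPanel,
    sheet: SampleSheet,
) -> AncestryResult:
    """Tally species-diagnostic alleles at AIM loci per sample and chromosome.

    ``source`` may be filtered genotype calls (default mode: each called
    haplotype contributes one allele observation) or pileup counts (each
    read contributes one observation). Fractions are species-A observations
    over informative observations (A + B).
    """
    if len(panel) == 0:
        raise ValidationError("AIM panel is empty")
    if isinstance(source, CalledVariants):
        rows = _from_calls(source, panel, sheet)
    else:
        rows = _from_pileup(source, panel, sheet)
    per_chrom = pd.DataFrame(
        rows,
        columns=["sample", "group", "chrom", "n_called", "count_a", "count_b",
                 "count_other"],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        informative = per_chrom["count_a"] + per_chrom["count_b"]
        per_chrom["fraction_a"] = np.where(
            informative > 0, per_chrom["count_a"] / informative, np.nan
        )
    per_sample = (
        per_chrom.groupby(["sample", "group"], sort=False)[
            ["n_called", "count_a", "count_b", "count_other"]
        ]
        .sum()
        .reset_index()
    )
    informative = per_sample["count_a"] + per_sample["count_b"]
    per_sample["fraction_a"] = np.where(
        informative > 0, per_sample["count_a"] / informative, np.nan
    )
    per_group = (
        per_sample.groupby("group", sort=True)
        .agg(fraction_a=("fraction_a", "mean"), n_called=("n_called", "sum"))
        .reset_index()
    )
    return AncestryResult(
        panel_label=panel.label,
        per_chrom=per_chrom,
        per_sample=per_sample,
        per_group=per_group,
    )


def _from_calls(v: CalledVariants, panel: AIMPanel, sheet: SampleSheet) -> list:
    site_index = {(c, int(p)): i for i, (c, p) in enumerate(zip(v.chrom, v.pos))}
    chroms = sorted({l.chrom for l in panel.loci})
    rows = []
    for sample in sheet.samples:
        j = v.samples.index(sample)
        group = sheet.group_of(sample)
        for chrom in chroms:
            n_called = count_a = count_b = count_other = 0
            for locus in panel.loci:
                if locus.chrom != chrom:
                    continue
                i = site_index.get((locus.chrom, locus.pos))
                if i is None:
                    continue
                alleles = v.alleles_at(i)
                calls = [a for a in v.genotypes[i, j] if a != MISSING]
                if not calls:
                    continue
                n_called += 1
                for a in calls:
                    base = alleles[a] if a < len(alleles) else None
                    if base == locus.allele_a:
                        count_a += 1
                    elif base == locus.allele_b:
                        count_b += 1
                    else:
                        count_other += 1
            rows.append((sample, group, chrom, n_called, count_a, count_b,
                         count_other))
    return rows


def _from_pileup(p: PileupCounts, panel: AIMPanel, sheet: SampleSheet) -> list:
    chroms = sorted({l.chrom for l in panel.loci})
    rows = []
    for sample in sheet.samples:
        group = sheet.group_of(sample)
        for chrom in chroms:
            n_called = count_a = count_b = count_other = 0
            for locus in panel.loci:
                if locus.chrom != chrom:
                    continue
                counts = p.counts_at(sample, locus.chrom, locus.pos)
                if counts is None or sum(counts.values()) == 0:
                    continue
                n_called += 1
                count_a += counts[locus.allele_a]
                count_b += counts[locus.allele_b]
                count_other += sum(
                    c for b, c in counts.items()
                    if b not in (locus.allele_a, locus.allele_b)
                )
            rows.append((sample, group, chrom, n_called, count_a, count_b,
                         count_other))
    return rows
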