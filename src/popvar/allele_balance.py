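"""Expressed allele balance at variants of interest, from read pileups.

The frequency of an allele here is its fraction of aligned reads at the
position — computed directly from pileup base counts, not from called
genotypes. Group summaries are unweighted means over covered replicates
(a depth-weighted variant is available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import SampleSheet, ValidationError, VOIPanel

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: Replicate states beyond a plain frequency.
NOT_DETECTED = "NOT_DETECTED"   # covered but zero alt reads
NO_COVERAGE = "NO_COVERAGE"     # zero depth


@dataclass
class PileupCounts:
    """Per sample x position A/C/G/T read counts.

    Backed by a long-format frame with columns sample, chrom, pos, A, C, G,
    T. Duplicate (sample, chrom, pos) rows are summed on construction, so
    counts split across rows are equivalent to a single summed row.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "chrom", "pos", *BASES]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"pileup table missing column(s) {missing}")
        df = self.table.copy()
        df["pos"] = df["pos"].astype(np.int64)
        for b in BASES:
            df[b] = df[b].astype(np.int64)
            if (df[b] < 0).any():
                raise ValidationError(f"negative read count in column {b}")
        df = df.groupby(["sample", "chrom", "pos"], as_index=False)[list(BASES)].sum()
        df["depth"] = df[list(BASES)].sum(axis=1)
        self.table = df

    def counts_at(self, sample: str, chrom: str, pos: int) -> dict[str, int] | None:
        sel = self.table[
            (self.table["sample"] == sample)
            & (self.table["chrom"] == chrom)
            & (self.table["pos"] == pos)
        ]
        if sel.empty:
            return None
        row = sel.iloc[0]
        return {b: int(row[b]) for b in BASES}

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique())


def read_pileup_counts(path: str | Path) -> PileupCounts:
    """Read a precomputed count TSV (sample, chrom, pos, A, C, G, T)."""
    return PileupCounts(table=pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str}))


def collect_pileup(
    source: str | Path | dict[str, str | Path] | PileupCounts,
    panel,
    min_base_quality: int = 13,
    min_mapping_quality: int = 1,
) -> PileupCounts:
    """Base counts at panel loci from a count TSV or indexed BAM file(s).

    ``source`` may be a PileupCounts, a path to a count TSV, or a mapping
    sample -> BAM path. Duplicate-flagged reads are excluded in BAM mode.
    Default read filters (BQ >= 13, MQ >= 1) follow conventional pileup
    practice.
    """
    loci = _panel_loci(panel)
    if isinstance(source, PileupCounts):
        return _restrict(source, loci)
    if isinstance(source, (str, Path)):
        return _restrict(read_pileup_counts(source), loci)
    # mapping of sample -> BAM
    import pysam

    rows = []
    for sample, bam_path in source.items():
        with pysam.AlignmentFile(str(bam_path)) as bam:
            refs = set(bam.references)
            for chrom, pos in loci:
                if chrom not in refs:
                    raise ValidationError(
                        f"locus contig {chrom!r} not present in alignment for {sample}"
                    )
                counts = dict.fromkeys(BASES, 0)
                for col in bam.pileup(
                    chrom, pos - 1, pos,
                    truncate=True,
                    min_base_quality=min_base_quality,
                    min_mapping_quality=min_mapping_quality,
                    ignore_overlaps=False,
                ):
                    if col.reference_pos != pos - 1:
                        continue
                    for read in col.pileups:
                        if read.is_del or read.is_refskip:
                            continue
                        if read.alignment.is_duplicate:
                            continue
                        base = read.alignment.query_sequence[read.query_position].upper()
                        if base in counts:
                            counts[base] += 1
                rows.append((sample, chrom, pos, *[counts[b] for b in BASES]))
    return PileupCounts(
        table=pd.DataFrame(rows, columns=["sample", "chrom", "pos", *BASES])
    )


def _panel_loci(panel) -> list[tuple[str, int]]:
    if isinstance(panel, VOIPanel):
        return [(l.chrom, l.pos) for l in panel.loci]
    if hasattr(panel, "tags"):  # TagSNPPanel
        return [(panel.chrom, t.pos) for t in panel.tags]
    if hasattr(panel, "loci"):  # AIMPanel
        return [(l.chrom, l.pos) for l in panel.loci]
    raise ValidationError(f"unsupported panel type {type(panel).__name__}")


def _restrict(p: PileupCounts, loci: list[tuple[str, int]]) -> PileupCounts:
    keys = set(loci)
    mask = [
        (c, int(q)) in keys
        for c, q in zip(p.table["chrom"], p.table["pos"])
    ]
    return PileupCounts(table=p.table[mask].reset_index(drop=True))


@dataclass
class AlleleBalanceResult:
    """Per-replicate and group-averaged expressed allele balance.

    ``per_sample`` columns: sample, group, name, chrom, pos, depth,
    ref_count, alt_count, other_count, frequency (NaN when uncovered),
    state ("OK" | NOT_DETECTED | NO_COVERAGE).
    ``per_group`` columns: group, name, frequency, ci_low, ci_high,
    n_covered.
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame


def allele_balance(
    p: PileupCounts,
    panel: VOIPanel,
    sheet: SampleSheet,
    depth_weighted: bool = False,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> AlleleBalanceResult:
    """Expressed allele balance per replicate and averaged per group.

    Per replicate f = alt reads / depth; only the panel's stated alt base
    counts toward f — reads for a third base are tallied separately. The
    group mean is the unweighted mean of f over replicates with depth > 0
    (depth-weighted pooling optional), with a seeded percentile-bootstrap
    95% CI over replicates.
    """
    rows = []
    for voi in panel.loci:
        for sample in sheet.samples:
            counts = p.counts_at(sample, voi.chrom, voi.pos)
            if counts is None:
                counts = dict.fromkeys(BASES, 0)
            depth = sum(counts.values())
            alt = counts[voi.alt_base]
            ref = counts[voi.ref_base]
            other = depth - alt - ref
            if depth == 0:
                state, freq = NO_COVERAGE, np.nan
            elif alt == 0:
                state, freq = NOT_DETECTED, 0.0
            else:
                state, freq = "OK", alt / depth
            rows.append((sample, sheet.group_of(sample), voi.name, voi.chrom,
                         voi.pos, depth, ref, alt, other, freq, state))
    per_sample = pd.DataFrame(
        rows,
        columns=["sample", "group", "name", "chrom", "pos", "depth",
                 "ref_count", "alt_count", "other_count", "frequency", "state"],
    )

    rng = np.random.default_rng(seed)
    grows = []
    for (group, name), sub in per_sample.groupby(["group", "name"], sort=True):
        covered = sub[sub["depth"] > 0]
        if covered.empty:
            grows.append((group, name, np.nan, np.nan, np.nan, 0))
            continue
        if depth_weighted:
            mean = covered["alt_count"].sum() / covered["depth"].sum()
        else:
            mean = covered["frequency"].mean()
        freqs = covered["frequency"].to_numpy()
        if len(freqs) > 1:
            idx = rng.integers(0, len(freqs), size=(n_bootstrap, len(freqs)))
            means = freqs[idx].mean(axis=1)
            lo, hi = np.percentile(means, [2.5, 97.5])
        else:
            lo = hi = freqs[0]
        grows.append((group, name, float(mean), float(lo), float(hi), len(covered)))
    per_group = pd.DataFrame(
        grows,
        columns=["group", "name", "frequency", "ci_low", "ci_high", "n_covered"],
    )
    return AlleleBalanceResult(per_sample=per_sample, per_group=per_group)
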