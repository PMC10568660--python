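"""Reading and validation of sample metadata, configuration, VCF, GFF3 and marker files.

Coordinates are 1-based inclusive throughout (matching VCF/GFF3); interval
intersections that require half-open semantics convert locally. Contig names
are taken verbatim from the input files — no normalization is applied, and a
contig-name mismatch between inputs is an error rather than an empty join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger(__name__)

#: Sentinel allele index marking a missing haplotype call. Distinct from 0
#: (homozygous reference) by construction; tested by invariant.
MISSING = -1

VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input file violates its contract."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Validated sample metadata: one row per sample with a treatment group.

    Extra columns beyond ``sampleID`` and ``treatment`` are preserved as
    opaque strings in :attr:`table`.
    """

    table: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.table["sampleID"])

    @property
    def groups(self) -> dict[str, list[str]]:
        """Mapping of treatment group -> ordered list of its sample ids."""
        out: dict[str, list[str]] = {}
        for sid, grp in zip(self.table["sampleID"], self.table["treatment"]):
            out.setdefault(grp, []).append(sid)
        return out

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sampleID"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return row["treatment"].iloc[0]

    def __len__(self) -> int:
        return len(self.table)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a tab-separated sample sheet with ``sampleID`` and ``treatment`` columns.

    Raises
    ------
    ValidationError
        If a required column is absent, a sample id is duplicated or empty,
        or a sample lacks a treatment group.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sampleID", "treatment"):
        if col not in df.columns:
            raise ValidationError(f"sample sheet is missing required column {col!r}")
    if df.empty:
        raise ValidationError("sample sheet contains no samples")
    ids = df["sampleID"]
    if ids.isna().any() or (ids.str.strip() == "").any():
        raise ValidationError("sample sheet contains an empty sampleID")
    dups = ids[ids.duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"duplicate sample id(s): {', '.join(dups)}")
    if df["treatment"].isna().any() or (df["treatment"].str.strip() == "").any():
        bad = df.loc[
            df["treatment"].isna() | (df["treatment"].str.strip() == ""), "sampleID"
        ].tolist()
        raise ValidationError(f"sample(s) without treatment group: {', '.join(bad)}")
    return SampleSheet(table=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Run parameters controlling filtering, windows, contrasts and seeds.

    ``ploidy`` is haplotypes per sample; pooled samples use 2 x pool size.
    """

    ploidy: int = 2
    qual_min: float = 30.0
    max_missing_fraction: float = 0.0
    window_size_bp: int = 20_000
    window_step_bp: int | None = None  # None => nonoverlapping tiling
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    pbs_triples: list[tuple[str, str, str]] = field(default_factory=list)
    ld_window_snps: int = 500
    ld_step_snps: int = 250
    ld_r2_threshold: float = 0.01
    fst_top_percentile: float = 5.0
    random_seed: int = 42

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValidationError(f"ploidy must be positive, got {self.ploidy}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValidationError("max_missing_fraction must lie in [0, 1]")
        if self.window_size_bp <= 0:
            raise ValidationError("window_size_bp must be positive")
        if not 0.0 <= self.ld_r2_threshold <= 1.0:
            raise ValidationError("ld_r2_threshold must lie in [0, 1]")
        self.contrasts = [tuple(c) for c in self.contrasts]
        self.pbs_triples = [tuple(t) for t in self.pbs_triples]

    _KEYS = (
        "ploidy", "qual_min", "max_missing_fraction", "window_size_bp",
        "window_step_bp", "contrasts", "pbs_triples", "ld_window_snps",
        "ld_step_snps", "ld_r2_threshold", "fst_top_percentile", "random_seed",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._KEYS)
        if unknown:
            raise ValidationError(
                f"invalid config key(s) {sorted(unknown)}; valid keys: {list(cls._KEYS)}"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self._KEYS}
        data["contrasts"] = [list(c) for c in self.contrasts]
        data["pbs_triples"] = [list(t) for t in self.pbs_triples]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate_groups(self, sheet: SampleSheet) -> None:
        known = set(sheet.groups)
        for pair in self.contrasts:
            for g in pair:
                if g not in known:
                    raise ValidationError(f"contrast group {g!r} not in sample sheet")
        for triple in self.pbs_triples:
            for g in triple:
                if g not in known:
                    raise ValidationError(f"PBS group {g!r} not in sample sheet")


# ---------------------------------------------------------------------------
# Called variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """A single variant record (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    effect_annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValidationError("ref allele must be non-empty")
        if not self.alt_alleles:
            raise ValidationError("at least one alt allele required")


@dataclass
class CalledVariants:
    """Genotype store: sites x samples x ploidy allele indices.

    ``genotypes[i, j, k]`` is the allele index (0 = ref, 1.. = alts) of the
    k-th haplotype of sample j at site i, or :data:`MISSING`. Sites are
    sorted by (chrom, pos) with duplicate identical records collapsed.
    """

    chrom: np.ndarray            # (n_sites,) str
    pos: np.ndarray              # (n_sites,) int64, 1-based
    ref: np.ndarray              # (n_sites,) str
    alt: list[tuple[str, ...]]   # per-site alt alleles
    qual: np.ndarray             # (n_sites,) float64
    genotypes: np.ndarray        # (n_sites, n_samples, ploidy) int16
    samples: list[str]
    ann: list[tuple[str, ...]] | None = None
    contigs: dict[str, int | None] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ploidy(self) -> int:
        return self.genotypes.shape[2]

    @property
    def sites(self) -> list[VariantSite]:
        ann = self.ann if self.ann is not None else [()] * self.n_sites
        return [
            VariantSite(c, int(p), r, tuple(a), float(q), tuple(an))
            for c, p, r, a, q, an in zip(
                self.chrom, self.pos, self.ref, self.alt, self.qual, ann
            )
        ]

    def n_alt(self) -> np.ndarray:
        return np.array([len(a) for a in self.alt], dtype=np.int64)

    def missing_fraction(self) -> np.ndarray:
        """Per site, the fraction of samples with any missing haplotype call."""
        any_missing = (self.genotypes == MISSING).any(axis=2)
        return any_missing.mean(axis=1)

    def is_snp(self) -> np.ndarray:
        """True where the ref and every alt allele have length 1."""
        return np.array(
            [len(r) == 1 and all(len(a) == 1 for a in alts)
             for r, alts in zip(self.ref, self.alt)],
            dtype=bool,
        )

    def take_sites(self, index: np.ndarray) -> "CalledVariants":
        index = np.asarray(index)
        return CalledVariants(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in index],
            qual=self.qual[index],
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            ann=None if self.ann is None else [self.ann[i] for i in index],
            contigs=dict(self.contigs),
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "CalledVariants":
        idx = [self.samples.index(s) for s in sample_ids]
        return replace(
            self,
            genotypes=self.genotypes[:, idx, :],
            samples=list(sample_ids),
            alt=list(self.alt),
            ann=None if self.ann is None else list(self.ann),
            contigs=dict(self.contigs),
        )

    def alleles_at(self, i: int) -> tuple[str, ...]:
        return (str(self.ref[i]),) + tuple(self.alt[i])

    def write_vcf(self, path: str | Path) -> None:
        """Write a plain-text VCF v4.2 preserving sites, genotypes and QUAL."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            contigs = self.contigs or {c: None for c in dict.fromkeys(self.chrom)}
            for name, length in contigs.items():
                if length is None:
                    fh.write(f"##contig=<ID={name}>\n")
                else:
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            if self.ann is not None:
                fh.write(
                    '##INFO=<ID=ANN,Number=.,Type=String,'
                    'Description="Functional annotations">\n'
                )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples) + "\n"
            )
            for i in range(self.n_sites):
                info = "."
                if self.ann is not None and self.ann[i]:
                    info = "ANN=" + ",".join(self.ann[i])
                qual = "." if np.isnan(self.qual[i]) else f"{self.qual[i]:g}"
                gts = []
                for j in range(self.n_samples):
                    calls = self.genotypes[i, j]
                    gts.append("/".join("." if a == MISSING else str(a) for a in calls))
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\t{self.ref[i]}\t"
                    f"{','.join(self.alt[i])}\t{qual}\t.\t{info}\tGT\t"
                    + "\t".join(gts) + "\n"
                )


def load_vcf(
    path: str | Path, sheet: SampleSheet, config: AnalysisConfig
) -> CalledVariants:
    """Load a VCF, restrict to the sheet's samples, sort and deduplicate.

    Raises
    ------
    ValidationError
        If a sheet sample is absent from the VCF or a genotype's ploidy
        disagrees with ``config.ploidy``.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    missing = [s for s in sheet.samples if s not in vcf_samples]
    if missing:
        raise ValidationError(
            f"sample(s) in sheet absent from VCF: {', '.join(missing)}"
        )
    contigs: dict[str, int | None] = {
        name: (ctg.length if ctg.length else None)
        for name, ctg in vf.header.contigs.items()
    }
    has_ann_header = "ANN" in vf.header.info

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    quals: list[float] = []
    anns: list[tuple[str, ...]] = []
    gts: list[list[tuple[int, ...]]] = []
    any_ann = False

    for rec in vf:
        alt = tuple(rec.alts) if rec.alts else ()
        if not alt:
            continue
        row: list[tuple[int, ...]] = []
        for s in sheet.samples:
            gt = rec.samples[s].get("GT", (None,))
            if gt is None or all(a is None for a in gt):
                row.append((MISSING,) * config.ploidy)
                continue
            if len(gt) != config.ploidy:
                raise ValidationError(
                    f"ploidy mismatch at {rec.chrom}:{rec.pos} sample {s}: "
                    f"observed {len(gt)}, configured {config.ploidy}"
                )
            row.append(tuple(MISSING if a is None else int(a) for a in gt))
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(alt)
        quals.append(float(rec.qual) if rec.qual is not None else np.nan)
        ann = rec.info.get("ANN", None) if has_ann_header else None
        if ann is not None:
            any_ann = True
            anns.append(tuple(ann) if not isinstance(ann, str) else (ann,))
        else:
            anns.append(())
        gts.append(row)
    vf.close()

    if not chroms:
        raise ValidationError(f"VCF {path} contains no variant records")

    # sort by (chrom, pos), then drop duplicate identical records (vcfuniq)
    order = sorted(range(len(poss)), key=lambda i: (chroms[i], poss[i]))
    seen: set[tuple] = set()
    keep: list[int] = []
    for i in order:
        key = (chroms[i], poss[i], refs[i], alts[i])
        if key in seen:
            continue
        seen.add(key)
        keep.append(i)

    genotypes = np.array([gts[i] for i in keep], dtype=np.int16)
    return CalledVariants(
        chrom=np.array([chroms[i] for i in keep], dtype=object),
        pos=np.array([poss[i] for i in keep], dtype=np.int64),
        ref=np.array([refs[i] for i in keep], dtype=object),
        alt=[alts[i] for i in keep],
        qual=np.array([quals[i] for i in keep], dtype=np.float64),
        genotypes=genotypes,
        samples=list(sheet.samples),
        ann=[anns[i] for i in keep] if any_ann else None,
        contigs=contigs,
    )


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterReport:
    """Counts of sites failing each filter (masks evaluated independently)."""

    n_input: int
    n_retained: int
    n_fail_snp: int
    n_fail_qual: int
    n_fail_missing: int


def filter_variants(
    v: CalledVariants, config: AnalysisConfig
) -> tuple[CalledVariants, FilterReport]:
    """Retain SNPs with QUAL >= qual_min and missingness <= max_missing_fraction.

    The QUAL threshold is inclusive. Filter masks are evaluated
    independently of each other, so the filters commute and the operation
    is idempotent. An empty result is allowed.
    """
    if v.n_sites == 0:
        return v, FilterReport(0, 0, 0, 0, 0)
    snp = v.is_snp()
    qual_ok = np.nan_to_num(v.qual, nan=-np.inf) >= config.qual_min
    # tolerate float representation of the fraction at the boundary
    miss_ok = v.missing_fraction() <= config.max_missing_fraction + 1e-12
    keep = snp & qual_ok & miss_ok
    report = FilterReport(
        n_input=v.n_sites,
        n_retained=int(keep.sum()),
        n_fail_snp=int((~snp).sum()),
        n_fail_qual=int((~qual_ok).sum()),
        n_fail_missing=int((~miss_ok).sum()),
    )
    return v.take_sites(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Grouped allele counts
# ---------------------------------------------------------------------------

@dataclass
class GroupedAlleleCounts:
    """Per-treatment-group allele count matrices: the substrate of popgen stats.

    ``counts[group]`` has shape (n_sites, n_alleles) where column 0 is the
    reference allele; ``n_i = counts.sum(axis=1)`` is the per-site number of
    non-missing haplotypes in the group.
    """

    chrom: np.ndarray
    pos: np.ndarray
    counts: dict[str, np.ndarray]

    @property
    def groups(self) -> list[str]:
        return list(self.counts)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def n(self, group: str) -> np.ndarray:
        return self.counts[group].sum(axis=1)

    def alt_freq(self, group: str) -> np.ndarray:
        """Total alt-allele frequency per site; NaN where no haplotypes called."""
        c = self.counts[group]
        n = c.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, c[:, 1:].sum(axis=1) / n, np.nan)


def group_allele_counts(v: CalledVariants, sheet: SampleSheet) -> GroupedAlleleCounts:
    """Count alleles per group over all non-missing haplotype calls."""
    if v.n_sites == 0:
        raise ValidationError("cannot count alleles on an empty variant set")
    n_alleles = int(1 + v.n_alt().max())
    counts: dict[str, np.ndarray] = {}
    for group, sample_ids in sheet.groups.items():
        idx = [v.samples.index(s) for s in sample_ids]
        g = v.genotypes[:, idx, :].reshape(v.n_sites, -1)  # (sites, haplotypes)
        mat = np.zeros((v.n_sites, n_alleles), dtype=np.int64)
        for a in range(n_alleles):
            mat[:, a] = (g == a).sum(axis=1)
        counts[group] = mat
    return GroupedAlleleCounts(chrom=v.chrom.copy(), pos=v.pos.copy(), counts=counts)


def biallelic_pair(
    gac: GroupedAlleleCounts, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce two groups' counts to (ref, most-frequent-alt) columns.

    Multiallelic sites are reduced to the alt allele most frequent in the
    two groups combined; the reduction count is logged. Returns two
    (n_sites, 2) arrays.
    """
    ca, cb = gac.counts[group_a], gac.counts[group_b]
    tot_alt = ca[:, 1:] + cb[:, 1:]
    top = np.argmax(tot_alt, axis=1) + 1
    n_multi = int((np.count_nonzero(tot_alt, axis=1) > 1).sum())
    if n_multi:
        logger.info(
            "biallelic reduction: %d multiallelic site(s) reduced to "
            "ref vs most-frequent-alt", n_multi,
        )
    rows = np.arange(gac.n_sites)
    out_a = np.stack([ca[:, 0], ca[rows, top]], axis=1)
    out_b = np.stack([cb[:, 0], cb[rows, top]], axis=1)
    return out_a, out_b


# ---------------------------------------------------------------------------
# Marker panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantOfInterest:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    name: str
    aa_change: str | None = None


@dataclass(frozen=True)
class VOIPanel:
    loci: tuple[VariantOfInterest, ...]

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class TagSNP:
    pos: int
    inverted_allele: str


@dataclass(frozen=True)
class TagSNPPanel:
    inversion: str
    chrom: str
    start: int
    end: int
    tags: tuple[TagSNP, ...]

    def __len__(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class AIMLocus:
    chrom: str
    pos: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class AIMPanel:
    label: str
    loci: tuple[AIMLocus, ...]

    def __len__(self) -> int:
        return len(self.loci)


def _check_base(value: str, column: str, lineno: int) -> str:
    value = str(value).strip()
    if value not in VALID_BASES:
        raise ValidationError(
            f"malformed allele {value!r} in column {column!r} at line {lineno}"
        )
    return value


PANEL_KINDS = ("variants_of_interest", "tag_snps", "aims")


def read_marker_panel(path: str | Path, panel_kind: str):
    """Read a marker TSV, returning a typed panel sorted by (chrom, pos).

    ``variants_of_interest`` -> :class:`VOIPanel` (columns chrom, pos, ref,
    alt, name); ``tag_snps`` -> list of :class:`TagSNPPanel`, one per
    inversion (columns inversion, chrom, start_bp, end_bp, pos,
    inverted_allele); ``aims`` -> list of :class:`AIMPanel`, one per panel
    label (columns chrom, pos, alleleA, alleleB, panel).
    """
    if panel_kind not in PANEL_KINDS:
        raise ValidationError(f"unknown panel kind {panel_kind!r}; one of {PANEL_KINDS}")
    df = pd.read_csv(path, sep="\t", dtype=str)

    if panel_kind == "variants_of_interest":
        _require(df, ("chrom", "pos", "ref", "alt", "name"), path)
        loci = []
        names = set()
        for i, row in df.iterrows():
            lineno = i + 2  # header is line 1
            ref = _check_base(row["ref"], "ref", lineno)
            alt = _check_base(row["alt"], "alt", lineno)
            if row["name"] in names:
                raise ValidationError(f"duplicate VOI name {row['name']!r} at line {lineno}")
            names.add(row["name"])
            loci.append(
                VariantOfInterest(
                    chrom=row["chrom"], pos=int(row["pos"]), ref_base=ref,
                    alt_base=alt, name=row["name"],
                    aa_change=row.get("aa_change"),
                )
            )
        loci.sort(key=lambda l: (l.chrom, l.pos))
        return VOIPanel(loci=tuple(loci))

    if panel_kind == "tag_snps":
        _require(df, ("inversion", "chrom", "start_bp", "end_bp", "pos",
                      "inverted_allele"), path)
        panels = []
        for inv, sub in df.groupby("inversion", sort=True):
            chrom = sub["chrom"].iloc[0]
            start = int(sub["start_bp"].iloc[0])
            end = int(sub["end_bp"].iloc[0])
            tags = []
            for i, row in sub.iterrows():
                lineno = i + 2
                allele = _check_base(row["inverted_allele"], "inverted_allele", lineno)
                pos = int(row["pos"])
                if not start <= pos <= end:
                    raise ValidationError(
                        f"tag SNP at line {lineno} lies outside the {inv} "
                        f"breakpoint span {start}-{end}"
                    )
                tags.append(TagSNP(pos=pos, inverted_allele=allele))
            tags.sort(key=lambda t: t.pos)
            panels.append(TagSNPPanel(inversion=str(inv), chrom=chrom,
                                      start=start, end=end, tags=tuple(tags)))
        return panels

    # aims
    _require(df, ("chrom", "pos", "alleleA", "alleleB", "panel"), path)
    panels = []
    for label, sub in df.groupby("panel", sort=True):
        loci = []
        for i, row in sub.iterrows():
            lineno = i + 2
            a = _check_base(row["alleleA"], "alleleA", lineno)
            b = _check_base(row["alleleB"], "alleleB", lineno)
            if a == b:
                raise ValidationError(f"AIM alleles identical at line {lineno}")
            loci.append(AIMLocus(chrom=row["chrom"], pos=int(row["pos"]),
                                 allele_a=a, allele_b=b))
        loci.sort(key=lambda l: (l.chrom, l.pos))
        panels.append(AIMPanel(label=str(label), loci=tuple(loci)))
    return panels


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Genome annotation (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Gene spans and merged exon intervals extracted from a GFF3 file.

    ``genes`` columns: gene_id, chrom, start, end (1-based inclusive).
    ``exons[chrom]`` is an (n, 2) array of merged, sorted exon intervals.
    ``contig_lengths`` comes from ``##sequence-region`` directives when present.
    """

    genes: pd.DataFrame
    exons: dict[str, np.ndarray]
    contig_lengths: dict[str, int]

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            candidates = self.genes["gene_id"].tolist()
            near = sorted(candidates, key=lambda g: _similarity(g, gene_id))[-3:]
            raise ValidationError(
                f"unknown gene id {gene_id!r}; nearest ids: {', '.join(reversed(near))}"
            )
        r = row.iloc[0]
        return r["chrom"], int(r["start"]), int(r["end"])


def _similarity(a: str, b: str) -> float:
    import difflib

    return difflib.SequenceMatcher(None, a, b).ratio()


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    ivs = intervals[np.argsort(intervals[:, 0])]
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


def load_annotation(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 into gene spans, merged exons and contig lengths."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        genes.append((gid, g.seqid, g.start, g.end))
    exon_raw: dict[str, list[tuple[int, int]]] = {}
    for e in db.features_of_type("exon"):
        exon_raw.setdefault(e.seqid, []).append((e.start, e.end))
    exons = {
        chrom: merge_intervals(np.array(ivs, dtype=np.int64))
        for chrom, ivs in exon_raw.items()
    }
    contig_lengths: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                contig_lengths[parts[1]] = int(parts[3])
    return GenomeAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"]),
        exons=exons,
        contig_lengths=contig_lengths,
    )
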