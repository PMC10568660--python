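"""SNP feature classification, effect tallies, gene reports, hypergeometric
enrichment, sweep-interval overlap, gene-family summaries and shared-direction
gene sets.

Feature precedence is exon > intron > intergenic with isoform exons merged.
BH is the multiple-testing adjustment everywhere an adjusted p is emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import (
    CalledVariants,
    GenomeAnnotation,
    GroupedAlleleCounts,
    ValidationError,
    merge_intervals,
)

logger = logging.getLogger(__name__)

FEATURE_LABELS = ("exon", "intron", "intergenic")

#: Most-severe-effect precedence used to assign one class per variant.
EFFECT_SEVERITY = ("nonsense", "missense", "synonymous", "other")

_EFFECT_MAP = {
    "stop_gained": "nonsense",
    "stop_lost": "nonsense",
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
}


# ---------------------------------------------------------------------------
# Feature classification
# ---------------------------------------------------------------------------

@dataclass
class FeatureClassification:
    """Per-SNP feature labels plus SNP-set and genome-composition fractions."""

    labels: np.ndarray              # per SNP, one of FEATURE_LABELS
    snp_fractions: dict[str, float]
    genome_fractions: dict[str, float]


def _in_intervals(pos: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Membership of 1-based positions in merged sorted inclusive intervals."""
    if len(intervals) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(intervals[:, 0], pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] <= intervals[idx[ok], 1]
    return out


def genome_composition(annotation: GenomeAnnotation) -> dict[str, float]:
    """Exon/intron/intergenic base-pair fractions of the annotated genome.

    Requires contig lengths (``##sequence-region`` directives). Independent
    of any SNP set.
    """
    if not annotation.contig_lengths:
        raise ValidationError(
            "GFF3 lacks ##sequence-region directives; genome length unknown"
        )
    total = sum(annotation.contig_lengths.values())
    exon_bp = sum(
        int((iv[:, 1] - iv[:, 0] + 1).sum()) for iv in annotation.exons.values()
    )
    genic_bp = 0
    for chrom, sub in annotation.genes.groupby("chrom"):
        merged = merge_intervals(sub[["start", "end"]].to_numpy(dtype=np.int64))
        genic_bp += int((merged[:, 1] - merged[:, 0] + 1).sum())
    intron_bp = genic_bp - exon_bp
    return {
        "exon": exon_bp / total,
        "intron": intron_bp / total,
        "intergenic": (total - genic_bp) / total,
    }


def classify_snp_features(
    chrom: np.ndarray, pos: np.ndarray, annotation: GenomeAnnotation
) -> FeatureClassification:
    """Label each SNP position exon / intron / intergenic.

    A position inside any (merged) exon is an exon; otherwise inside a gene
    span it is an intron; otherwise intergenic. Contig names present in the
    positions but absent from the GFF3 raise an error rather than silently
    classifying everything intergenic.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    gff_contigs = set(annotation.genes["chrom"]) | set(annotation.exons) \
        | set(annotation.contig_lengths)
    unknown = sorted(set(chrom) - gff_contigs)
    if unknown:
        raise ValidationError(
            f"contig(s) {unknown} present in variants but absent from GFF3"
        )
    gene_ivs = {
        c: merge_intervals(sub[["start", "end"]].to_numpy(dtype=np.int64))
        for c, sub in annotation.genes.groupby("chrom")
    }
    labels = np.full(len(pos), "intergenic", dtype=object)
    for c in np.unique(chrom):
        sel = chrom == c
        p = pos[sel]
        in_exon = _in_intervals(p, annotation.exons.get(c, np.empty((0, 2), int)))
        in_gene = _in_intervals(p, gene_ivs.get(c, np.empty((0, 2), int)))
        lab = np.where(in_exon, "exon", np.where(in_gene, "intron", "intergenic"))
        labels[sel] = lab
    n = max(len(labels), 1)
    snp_fractions = {l: float((labels == l).sum()) / n for l in FEATURE_LABELS}
    return FeatureClassification(
        labels=labels,
        snp_fractions=snp_fractions,
        genome_fractions=genome_composition(annotation),
    )


# ---------------------------------------------------------------------------
# Effect annotation tallies
# ---------------------------------------------------------------------------

def _classify_ann(ann_entries: tuple[str, ...]) -> str | None:
    """Most severe effect class across a record's annotation entries."""
    classes = set()
    for entry in ann_entries:
        fields = entry.split("|")
        effects = fields[1] if len(fields) > 1 else entry
        for eff in effects.split("&"):
            classes.add(_EFFECT_MAP.get(eff.strip(), "other"))
    for cls in EFFECT_SEVERITY:
        if cls in classes:
            return cls
    return None


def tally_effects(v: CalledVariants) -> pd.DataFrame:
    """Fractions of nonsense/missense/synonymous/other among annotated variants.

    Each variant contributes one class, its most severe effect across
    transcripts. Annotations are parsed, never recomputed. Variants without
    an ANN entry are skipped; a VCF with no ANN anywhere is an error.
    """
    if v.ann is None or all(not a for a in v.ann):
        raise ValidationError(
            "no ANN annotations present; annotate the VCF (e.g. with snpEff) first"
        )
    counts = dict.fromkeys(EFFECT_SEVERITY, 0)
    for ann in v.ann:
        if not ann:
            continue
        cls = _classify_ann(ann)
        if cls is not None:
            counts[cls] += 1
    total = sum(counts.values())
    rows = [
        (cls, counts[cls], counts[cls] / total if total else np.nan)
        for cls in EFFECT_SEVERITY
    ]
    return pd.DataFrame(rows, columns=["effect", "count", "fraction"])


def gene_missense_report(
    v: CalledVariants,
    gene_id: str,
    annotation: GenomeAnnotation,
    gac: GroupedAlleleCounts | None = None,
) -> pd.DataFrame:
    """Missense variants within a gene span with per-group alt frequencies.

    Columns: chrom, pos, ref, alt, aa_change, then one frequency column per
    group when grouped counts are supplied. An unknown gene id raises an
    error listing the nearest known ids.
    """
    chrom, start, end = annotation.gene_span(gene_id)
    rows = []
    for i in range(v.n_sites):
        if v.chrom[i] != chrom or not (start <= v.pos[i] <= end):
            continue
        ann = v.ann[i] if v.ann is not None else ()
        if not ann or _classify_ann(ann) != "missense":
            continue
        aa = ""
        for entry in ann:
            fields = entry.split("|")
            if len(fields) > 10 and "missense" in fields[1]:
                aa = fields[10]
                break
        row = {
            "chrom": v.chrom[i], "pos": int(v.pos[i]), "ref": v.ref[i],
            "alt": ",".join(v.alt[i]), "aa_change": aa,
        }
        if gac is not None:
            site = int(np.flatnonzero((gac.chrom == v.chrom[i]) & (gac.pos == v.pos[i]))[0])
            for group in gac.groups:
                row[f"freq_{group}"] = float(gac.alt_freq(group)[site])
        rows.append(row)
    columns = ["chrom", "pos", "ref", "alt", "aa_change"]
    if gac is not None:
        columns += [f"freq_{g}" for g in gac.groups]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    selected: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term, BH-adjusted.

    ``annotation`` maps gene -> set of terms. For each term with K annotated
    genes in a universe of N, a selection of n genes containing k annotated
    ones scores p = P(X >= k). Selected genes must be a subset of the
    universe.
    """
    stray = sorted(selected - universe)
    if stray:
        raise ValidationError(f"selected gene(s) not in universe: {', '.join(stray)}")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in universe:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    n_pop = len(universe)
    n_sel = len(selected)
    rows = []
    for term, genes in sorted(term_genes.items()):
        big_k = len(genes)
        k = len(genes & selected)
        p = float(sps.hypergeom.sf(k - 1, n_pop, big_k, n_sel))
        rows.append((term, n_pop, big_k, n_sel, k, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "N_pop", "K_annotated", "n_selected", "k", "p_value"]
    )
    if len(out):
        out["p_adjusted"] = sps.false_discovery_control(
            out["p_value"].to_numpy(), method="bh"
        )
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Sweep-interval overlap
# ---------------------------------------------------------------------------

SWEEP_CAVEAT = (
    "exploratory: many genes fall within selective sweeps and may have no "
    "causal link to phenotypic variation"
)


def sweep_overlap(genes: pd.DataFrame, sweeps: pd.DataFrame) -> pd.DataFrame:
    """Half-open interval intersection of gene spans with sweep records.

    ``genes``: gene_id, chrom, start, end. ``sweeps``: chrom, start, end,
    signal, cohort. Intervals are treated as half-open [start, end): an
    interval ending where another starts does not overlap. Symmetric in
    which table is query vs subject. Output rows carry the exploratory
    caveat string.
    """
    rows = []
    for _, g in genes.iterrows():
        for _, s in sweeps.iterrows():
            if g["chrom"] != s["chrom"]:
                continue
            if max(g["start"], s["start"]) < min(g["end"], s["end"]):
                rows.append((g["gene_id"], g["chrom"], g["start"], g["end"],
                             s["signal"], s["cohort"], s["start"], s["end"],
                             SWEEP_CAVEAT))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "gene_start", "gene_end", "signal",
                 "cohort", "sweep_start", "sweep_end", "caveat"],
    )


# ---------------------------------------------------------------------------
# Gene-family expression summaries
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilySummary:
    """Hierarchically ordered family members with counts and fold-changes."""

    family: str
    members: list[str]          # clustering leaf order
    linkage: np.ndarray | None  # scipy linkage matrix, None for <2 members
    counts: pd.DataFrame        # normalized counts, rows in leaf order
    fold_changes: pd.DataFrame | None


def gene_family_summary(
    counts: pd.DataFrame,
    pfam_map: pd.DataFrame,
    family: str,
    fold_changes: pd.DataFrame | None = None,
) -> GeneFamilySummary:
    """Cluster a PFAM family's genes on normalized counts.

    ``counts`` is genes x samples (index = gene ids); ``pfam_map`` has
    columns gene_id, family. Correlation distance with average linkage
    orders the members; families with fewer than 2 members in the data get
    the identity ordering and no dendrogram.
    """
    members = pfam_map.loc[pfam_map["family"] == family, "gene_id"].tolist()
    present = [g for g in members if g in counts.index]
    if not present:
        raise ValidationError(f"no genes of family {family!r} found in the count matrix")
    sub = counts.loc[present]
    if len(present) < 2:
        return GeneFamilySummary(
            family=family, members=present, linkage=None, counts=sub,
            fold_changes=_subset_fc(fold_changes, present),
        )
    x = sub.to_numpy(dtype=float)
    corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(link)
    ordered = [present[i] for i in order]
    return GeneFamilySummary(
        family=family, members=ordered, linkage=link,
        counts=sub.loc[ordered],
        fold_changes=_subset_fc(fold_changes, ordered),
    )


def _subset_fc(fold_changes: pd.DataFrame | None, genes: list[str]):
    if fold_changes is None:
        return None
    return fold_changes[fold_changes["gene_id"].isin(genes)].set_index("gene_id") \
        .reindex(genes).reset_index()


#: Default families summarized when none are specified.
DEFAULT_FAMILIES = (
    "cytochrome_P450",
    "GST",
    "carboxylesterase",
    "ABC_transporter",
    "odorant_binding_protein",
    "olfactory_receptor",
    "ionotropic_receptor",
    "gustatory_receptor",
    "cuticle",
)


# ---------------------------------------------------------------------------
# Shared-direction gene sets and venn counts
# ---------------------------------------------------------------------------

def shared_direction_genes(
    tables: dict[str, pd.DataFrame],
    direction: str = "up",
    padj_threshold: float = 0.05,
) -> tuple[set[str], dict[str, int]]:
    """Genes significant and same-signed across all comparisons, plus venn counts.

    Each table needs columns gene_id, log2fc, padj. ``direction`` is "up"
    (log2fc > 0) or "down". Venn region counts are keyed by sorted
    comma-joined comparison names for every nonempty combination.
    """
    if len(tables) < 2:
        raise ValidationError("need at least 2 comparisons")
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    sig: dict[str, set[str]] = {}
    for name, df in tables.items():
        mask = (df["padj"] < padj_threshold) & (
            df["log2fc"] > 0 if direction == "up" else df["log2fc"] < 0
        )
        sig[name] = set(df.loc[mask, "gene_id"])
    names = sorted(sig)
    shared = set.intersection(*(sig[n] for n in names))
    # exclusive venn region counts
    venn: dict[str, int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sig[n] for n in combo))
            outside = set.union(
                *(sig[n] for n in names if n not in combo), set()
            )
            venn[",".join(combo)] = len(inside - outside)
    return shared, venn
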