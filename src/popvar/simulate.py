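"""Synthetic-data generation with known ground truth for every estimator.

Population differentiation follows the Balding-Nichols model: per site an
ancestral frequency p ~ Uniform(0.05, 0.95) and, per population, an allele
frequency drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) — chosen because the
expected ratio-of-averages Hudson estimate equals F, giving an analytic
recovery anchor. A single global seed fans out to per-component seeds via
``numpy.random.SeedSequence.spawn`` so components can be regenerated
independently and every artifact is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AIMLocus,
    AIMPanel,
    AnalysisConfig,
    CalledVariants,
    SampleSheet,
    TagSNP,
    TagSNPPanel,
    ValidationError,
    VariantOfInterest,
    VOIPanel,
)
from .allele_balance import BASES, PileupCounts

_NUCS = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the generator; the seed fixes all randomness."""

    n_pops: int = 2
    f_target: float = 0.1
    #: optional per-population drift levels overriding f_target (length n_pops);
    #: lets a focal population sit at the ancestral frequencies (F = 0) while
    #: others drift, giving a zero-length focal branch for PBS checks
    f_per_pop: list[float] | None = None
    n_sites: int = 1000
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    n_samples_per_pop: int = 10
    ploidy: int = 2
    depth_mean: int = 50
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_target < 1.0:
            raise ValidationError("F must lie in [0, 1); F = 1 is degenerate")
        if self.f_per_pop is not None:
            if len(self.f_per_pop) != self.n_pops:
                raise ValidationError("f_per_pop length must equal n_pops")
            if any(not 0.0 <= f < 1.0 for f in self.f_per_pop):
                raise ValidationError("every F must lie in [0, 1)")
        if self.depth_mean < 0:
            raise ValidationError("depth must be non-negative")
        if self.n_sites > self.chrom_length:
            raise ValidationError("more sites than chromosome positions")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SimulatedPopulations:
    variants: CalledVariants
    sheet: SampleSheet
    true_freqs: pd.DataFrame  # chrom, pos, ancestral, then one column per pop


def simulate_populations(cfg: SimulationConfig) -> SimulatedPopulations:
    """Genotypes for ``n_pops`` populations differentiated at level F.

    Per site: ancestral p ~ U(0.05, 0.95); population frequency Beta-drawn
    (exactly p when F = 0); each sample's ploidy alleles are binomial draws
    at the population frequency. Ref/alt bases are random distinct
    nucleotides; QUAL is fixed at 60 so simulated sites pass the default
    filters.
    """
    rng_sites, rng_freq, rng_geno, rng_bases = _spawn(cfg.seed, 4)
    pos = np.sort(
        rng_sites.choice(np.arange(1, cfg.chrom_length + 1), size=cfg.n_sites,
                         replace=False)
    ).astype(np.int64)
    p_anc = rng_sites.uniform(0.05, 0.95, size=cfg.n_sites)

    pop_freqs = np.empty((cfg.n_pops, cfg.n_sites))
    f_levels = cfg.f_per_pop or [cfg.f_target] * cfg.n_pops
    for k, f in enumerate(f_levels):
        if f == 0.0:
            pop_freqs[k] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pop_freqs[k] = rng_freq.beta(a, b)

    n_total = cfg.n_pops * cfg.n_samples_per_pop
    genotypes = np.zeros((cfg.n_sites, n_total, cfg.ploidy), dtype=np.int16)
    for k in range(cfg.n_pops):
        q = pop_freqs[k][:, None]  # (sites, 1)
        draws = rng_geno.random((cfg.n_sites, cfg.n_samples_per_pop, cfg.ploidy))
        sl = slice(k * cfg.n_samples_per_pop, (k + 1) * cfg.n_samples_per_pop)
        genotypes[:, sl, :] = (draws < q[:, :, None]).astype(np.int16)

    ref_idx = rng_bases.integers(0, 4, size=cfg.n_sites)
    alt_shift = rng_bases.integers(1, 4, size=cfg.n_sites)
    refs = _NUCS[ref_idx]
    alts = _NUCS[(ref_idx + alt_shift) % 4]

    samples = [
        f"pop{k}_s{j}"
        for k in range(cfg.n_pops)
        for j in range(cfg.n_samples_per_pop)
    ]
    sheet = SampleSheet(pd.DataFrame({
        "sampleID": samples,
        "treatment": [
            f"pop{k}"
            for k in range(cfg.n_pops)
            for _ in range(cfg.n_samples_per_pop)
        ],
    }))
    variants = CalledVariants(
        chrom=np.array([cfg.chrom] * cfg.n_sites, dtype=object),
        pos=pos,
        ref=refs.astype(object),
        alt=[(a,) for a in alts],
        qual=np.full(cfg.n_sites, 60.0),
        genotypes=genotypes,
        samples=samples,
        contigs={cfg.chrom: cfg.chrom_length},
    )
    truth = pd.DataFrame({"chrom": cfg.chrom, "pos": pos, "ancestral": p_anc})
    for k in range(cfg.n_pops):
        truth[f"pop{k}"] = pop_freqs[k]
    return SimulatedPopulations(variants=variants, sheet=sheet, true_freqs=truth)


def simulate_pool_pileup(
    true_freqs: pd.DataFrame,
    samples: list[str],
    ref_bases: dict[tuple[str, int], str],
    alt_bases: dict[tuple[str, int], str],
    depth: int,
    error_rate: float = 0.0,
    seed: int = 0,
    freq_column: str = "q",
) -> PileupCounts:
    """Binomial read sampling at each locus for each pooled sample.

    ``true_freqs`` needs columns chrom, pos and ``freq_column`` (the true
    alt-allele frequency). Each read is alt with probability q, then
    sequencing error redirects it to one of the three other bases with
    probability ``error_rate`` (uniformly), so with error 0 and q = 1 all
    reads are alt.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        for _, rec in true_freqs.iterrows():
            chrom, pos = rec["chrom"], int(rec["pos"])
            q = float(rec[freq_column])
            if not 0.0 <= q <= 1.0:
                raise ValidationError(f"true frequency {q} outside [0, 1]")
            ref = ref_bases[(chrom, pos)]
            alt = alt_bases[(chrom, pos)]
            others = [b for b in BASES if b not in (ref, alt)]
            e = error_rate
            prob = dict.fromkeys(BASES, 0.0)
            prob[alt] += q * (1 - e)
            prob[ref] += (1 - q) * (1 - e)
            for src_p, src in ((q, alt), (1 - q, ref)):
                for b in BASES:
                    if b != src:
                        prob[b] += src_p * e / 3.0
            draw = rng.multinomial(depth, [prob[b] for b in BASES]) if depth > 0 \
                else np.zeros(4, dtype=int)
            rows.append((sample, chrom, pos, *draw.tolist()))
    return PileupCounts(
        table=pd.DataFrame(rows, columns=["sample", "chrom", "pos", *BASES])
    )


@dataclass
class SimulatedPanels:
    tag_panel: TagSNPPanel
    aim_panel: AIMPanel
    voi_panel: VOIPanel
    gff3_text: str
    genic_fraction: float
    exonic_fraction: float


def simulate_panels(
    cfg: SimulationConfig,
    n_tags: int = 200,
    inversion_span: tuple[int, int] = (1, 1_000_000),
    n_aims: int = 100,
    n_voi: int = 5,
    n_genes: int = 10,
    genic_fraction: float = 0.46,
    exonic_fraction: float = 0.14,
) -> SimulatedPanels:
    """Tag-SNP, AIM and VOI panels plus a toy GFF3 of known composition.

    Gene spans are laid out evenly so the merged genic fraction of the
    chromosome equals ``genic_fraction`` and each gene's first part is
    exonic such that the total exonic fraction equals ``exonic_fraction``.
    """
    if not 0 < exonic_fraction <= genic_fraction < 1:
        raise ValidationError("need 0 < exonic_fraction <= genic_fraction < 1")
    rng_tag, rng_aim, rng_voi = _spawn(cfg.seed + 1, 3)

    start, end = inversion_span
    tag_pos = np.sort(
        rng_tag.choice(np.arange(start, end + 1), size=n_tags, replace=False)
    )
    tag_alleles = _NUCS[rng_tag.integers(0, 4, size=n_tags)]
    tag_panel = TagSNPPanel(
        inversion="2La", chrom=cfg.chrom, start=start, end=end,
        tags=tuple(TagSNP(int(p), a) for p, a in zip(tag_pos, tag_alleles)),
    )

    aim_pos = np.sort(
        rng_aim.choice(np.arange(1, cfg.chrom_length + 1), size=n_aims, replace=False)
    )
    a_idx = rng_aim.integers(0, 4, size=n_aims)
    b_idx = (a_idx + rng_aim.integers(1, 4, size=n_aims)) % 4
    aim_panel = AIMPanel(
        label="speciesA_vs_speciesB",
        loci=tuple(
            AIMLocus(cfg.chrom, int(p), _NUCS[i], _NUCS[j])
            for p, i, j in zip(aim_pos, a_idx, b_idx)
        ),
    )

    voi_pos = np.sort(
        rng_voi.choice(np.arange(1, cfg.chrom_length + 1), size=n_voi, replace=False)
    )
    r_idx = rng_voi.integers(0, 4, size=n_voi)
    v_idx = (r_idx + rng_voi.integers(1, 4, size=n_voi)) % 4
    voi_panel = VOIPanel(
        loci=tuple(
            VariantOfInterest(cfg.chrom, int(p), _NUCS[i], _NUCS[j], f"voi{k}")
            for k, (p, i, j) in enumerate(zip(voi_pos, r_idx, v_idx))
        ),
    )

    # toy GFF3: n_genes evenly spaced genes of equal size
    gene_bp = int(round(cfg.chrom_length * genic_fraction / n_genes))
    exon_bp = int(round(cfg.chrom_length * exonic_fraction / n_genes))
    gap = (cfg.chrom_length - gene_bp * n_genes) // (n_genes + 1)
    lines = [
        "##gff-version 3",
        f"##sequence-region {cfg.chrom} 1 {cfg.chrom_length}",
    ]
    pos = gap + 1
    for g in range(n_genes):
        gstart, gend = pos, pos + gene_bp - 1
        estart, eend = gstart, gstart + exon_bp - 1
        lines.append(
            f"{cfg.chrom}\tsim\tgene\t{gstart}\t{gend}\t.\t+\t.\tID=gene{g}"
        )
        lines.append(
            f"{cfg.chrom}\tsim\tmRNA\t{gstart}\t{gend}\t.\t+\t.\t"
            f"ID=gene{g}.t1;Parent=gene{g}"
        )
        lines.append(
            f"{cfg.chrom}\tsim\texon\t{estart}\t{eend}\t.\t+\t.\t"
            f"ID=gene{g}.e1;Parent=gene{g}.t1"
        )
        pos = gend + gap + 1
    gff3_text = "\n".join(lines) + "\n"
    return SimulatedPanels(
        tag_panel=tag_panel, aim_panel=aim_panel, voi_panel=voi_panel,
        gff3_text=gff3_text,
        genic_fraction=gene_bp * n_genes / cfg.chrom_length,
        exonic_fraction=exon_bp * n_genes / cfg.chrom_length,
    )


def simulate_expression(
    sheet: SampleSheet,
    n_genes: int = 100,
    group_shift: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-shifted lognormal count table (genes x samples) for PCA tests."""
    rng = np.random.default_rng(seed)
    groups = sorted(sheet.groups)
    base = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)
    shifted_genes = rng.random(n_genes) < 0.3
    data = {}
    for sample in sheet.samples:
        g_idx = groups.index(sheet.group_of(sample))
        mu = base * np.where(shifted_genes, group_shift**g_idx, 1.0)
        data[sample] = rng.poisson(mu)
    return pd.DataFrame(data, index=[f"gene{i}" for i in range(n_genes)])


# ---------------------------------------------------------------------------
# File emission for the CLI `simulate` subcommand
# ---------------------------------------------------------------------------

def write_simulation(outdir: str | Path, cfg: SimulationConfig) -> dict[str, Path]:
    """Emit a directory of VCF, panels, GFF3, sheet, config and truth tables.

    Every file parses back through the core readers; ground-truth TSVs
    accompany each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_populations(cfg)
    panels = simulate_panels(cfg)

    paths: dict[str, Path] = {}
    paths["vcf"] = outdir / "variants.vcf"
    sim.variants.write_vcf(paths["vcf"])
    paths["samples"] = outdir / "samples.tsv"
    sim.sheet.table.to_csv(paths["samples"], sep="\t", index=False)
    paths["truth"] = outdir / "true_frequencies.tsv"
    sim.true_freqs.to_csv(paths["truth"], sep="\t", index=False)

    paths["gff3"] = outdir / "annotation.gff3"
    paths["gff3"].write_text(panels.gff3_text)

    tp = panels.tag_panel
    paths["tag_snps"] = outdir / "tag_snps.tsv"
    pd.DataFrame(
        [(tp.inversion, tp.chrom, tp.start, tp.end, t.pos, t.inverted_allele)
         for t in tp.tags],
        columns=["inversion", "chrom", "start_bp", "end_bp", "pos",
                 "inverted_allele"],
    ).to_csv(paths["tag_snps"], sep="\t", index=False)

    ap = panels.aim_panel
    paths["aims"] = outdir / "aims.tsv"
    pd.DataFrame(
        [(l.chrom, l.pos, l.allele_a, l.allele_b, ap.label) for l in ap.loci],
        columns=["chrom", "pos", "alleleA", "alleleB", "panel"],
    ).to_csv(paths["aims"], sep="\t", index=False)

    vp = panels.voi_panel
    paths["voi"] = outdir / "variants_of_interest.tsv"
    pd.DataFrame(
        [(l.chrom, l.pos, l.ref_base, l.alt_base, l.name) for l in vp.loci],
        columns=["chrom", "pos", "ref", "alt", "name"],
    ).to_csv(paths["voi"], sep="\t", index=False)

    paths["config"] = outdir / "config.yaml"
    groups = sorted(sim.sheet.groups)
    AnalysisConfig(
        ploidy=cfg.ploidy,
        contrasts=[(groups[0], groups[1])] if len(groups) >= 2 else [],
        random_seed=cfg.seed,
    ).to_yaml(paths["config"])
    return paths
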