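"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from popvar.core_io import AnalysisConfig, SampleSheet, read_sample_sheet


def write_vcf_text(path: Path, records: list[dict], samples: list[str],
                   contigs: dict[str, int] | None = None,
                   ann_header: bool = False) -> Path:
    """Write a minimal VCF v4.2 from record dicts.

    Each record: chrom, pos, ref, alt (comma-joined string), qual, gts
    (list of genotype strings like "0/1"), optional info.
    """
    lines = ["##fileformat=VCFv4.2"]
    contigs = contigs or {r["chrom"]: 10_000_000 for r in records}
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    if ann_header:
        lines.append('##INFO=<ID=ANN,Number=.,Type=String,Description="ann">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for r in records:
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
            f"{r['qual']}\t.\t{r.get('info', '.')}\tGT\t" + "\t".join(r["gts"])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def make_sheet(groups: dict[str, int]) -> SampleSheet:
    """A SampleSheet with the given group sizes; samples named <group>_<i>."""
    rows = [(f"{g}_{i}", g) for g, n in groups.items() for i in range(n)]
    return SampleSheet(pd.DataFrame(rows, columns=["sampleID", "treatment"]))


@pytest.fixture
def two_sample_sheet(tmp_path) -> SampleSheet:
    p = tmp_path / "samples.tsv"
    p.write_text("sampleID\ttreatment\nS1\tctrl\nS2\tctrl\n")
    return read_sample_sheet(p)


@pytest.fixture
def diploid_config() -> AnalysisConfig:
    return AnalysisConfig(ploidy=2)


@pytest.fixture
def toy_filter_vcf(tmp_path) -> Path:
    """The 5-record filter fixture: exactly 2 records survive the defaults.

    Records: SNP q=50 fully called (pass); indel q=60 (fail SNP); SNP q=20
    (fail QUAL); SNP q=45 with one missing genotype (fail missingness);
    SNP q=30 fully called (pass, inclusive boundary).
    """
    records = [
        {"chrom": "c1", "pos": 100, "ref": "A", "alt": "G", "qual": 50,
         "gts": ["0/1", "1/1"]},
        {"chrom": "c1", "pos": 200, "ref": "AT", "alt": "A", "qual": 60,
         "gts": ["0/0", "0/1"]},
        {"chrom": "c1", "pos": 300, "ref": "C", "alt": "T", "qual": 20,
         "gts": ["0/0", "0/1"]},
        {"chrom": "c1", "pos": 400, "ref": "G", "alt": "A", "qual": 45,
         "gts": ["./.", "0/1"]},
        {"chrom": "c1", "pos": 500, "ref": "T", "alt": "C", "qual": 30,
         "gts": ["0/1", "0/0"]},
    ]
    return write_vcf_text(tmp_path / "toy.vcf", records, ["S1", "S2"])


TOY_GFF = """##gff-version 3
##sequence-region c1 1 1000
c1\ttoy\tgene\t100\t400\t.\t+\t.\tID=geneA
c1\ttoy\tmRNA\t100\t400\t.\t+\t.\tID=geneA.t1;Parent=geneA
c1\ttoy\texon\t100\t200\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
c1\ttoy\tgene\t550\t608\t.\t-\t.\tID=geneB
c1\ttoy\tmRNA\t550\t608\t.\t-\t.\tID=geneB.t1;Parent=geneB
c1\ttoy\texon\t550\t608\t.\t-\t.\tID=geneB.e1;Parent=geneB.t1
c1\ttoy\tgene\t650\t749\t.\t+\t.\tID=geneC
c1\ttoy\tmRNA\t650\t749\t.\t+\t.\tID=geneC.t1;Parent=geneC
c1\ttoy\texon\t650\t699\t.\t+\t.\tID=geneC.e1;Parent=geneC.t1
"""


@pytest.fixture
def toy_gff(tmp_path) -> Path:
    """Toy annotation: merged genic span 301 + 59 + 100 = 460 of 1000 bp."""
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return p
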