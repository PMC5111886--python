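"""Serialization of synthetic truth to standard text formats.

Coordinates are 0-based half-open internally and converted to 1-based
inclusive on GFF3/VCF output. Indels are written VCF-style with the
anchoring base preceding the event.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List

import pandas as pd

from ..coords import Variant
from .genome import DiploidGenome, GeneModel


def write_fasta(seqs: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\thetkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\thetkit\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for j, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\thetkit\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.t1.e{j};"
                         f"Parent={g.gene_id}.t1\n")


def write_vcf(genome: DiploidGenome, path) -> None:
    """Planted hapA->hapB differences as a VCF against hapA."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome.hapA):
            fh.write(f"##contig=<ID={chrom},length={len(genome.hapA[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in sorted(genome.variants):
            seq = genome.hapA[chrom]
            for v in genome.variants[chrom]:
                if v.kind == "snp":
                    pos, ref, alt = v.pos + 1, v.ref, v.alt
                elif v.kind == "del":
                    if v.pos == 0:   # right-anchor when at sequence start
                        pos = 1
                        ref = v.ref + seq[v.pos + len(v.ref)]
                        alt = ref[-1]
                    else:
                        pos = v.pos
                        ref = seq[v.pos - 1] + v.ref
                        alt = seq[v.pos - 1]
                else:
                    if v.pos == 0:
                        pos = 1
                        ref = seq[0]
                        alt = v.alt + seq[0]
                    else:
                        pos = v.pos
                        ref = seq[v.pos - 1]
                        alt = seq[v.pos - 1] + v.alt
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                         f"TYPE={v.kind}\n")


def write_repeats_bed(genome: DiploidGenome, path) -> None:
    with open(path, "w") as fh:
        for r in genome.repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\n")


def gene_truth_table(genome: DiploidGenome) -> pd.DataFrame:
    """Per-gene planted polymorphism truth over exonic bases."""
    rows = []
    for g in genome.genes:
        vs = genome.variants[g.chrom]
        n_snp = n_indel = n_snp_span = n_indel_span = 0
        for v in vs:
            if g.start <= v.pos < g.end:
                if v.kind == "snp":
                    n_snp_span += 1
                else:
                    n_indel_span += 1
                if any(s <= v.pos < e for s, e in g.exons):
                    if v.kind == "snp":
                        n_snp += 1
                    else:
                        n_indel += 1
        exonic = g.spliced_length
        span = g.end - g.start
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "start": g.start, "end": g.end, "exonic_len": exonic,
            "n_snps": n_snp, "n_indels": n_indel,
            "true_het_pct": 100.0 * (n_snp + n_indel) / exonic,
            "span_len": span,
            "n_snps_span": n_snp_span, "n_indels_span": n_indel_span,
            "true_het_span_pct": 100.0 * (n_snp_span + n_indel_span) / span,
        })
    return pd.DataFrame(rows)
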