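"""End-to-end orchestration: synth -> kspec -> collapse -> hetcall ->
overlaps -> combin, from one YAML config, with a checksum manifest.

Config layout (all blocks optional; missing analysis blocks use defaults,
``stages`` restricts which stages run)::

    outdir: runs/demo
    seed: 1
    stages: [synth, kspec, collapse, hetcall, overlaps, combin]
    synth: { haploid_length: 200000, snp_rate: 0.025, ... }
    kspec: { k: 31 }
    collapse: { min_identity: 95.0, min_overlap: 0.95,
                piece_min: 5000, piece_max: 20000 }
    hetcall: { split_prob: 0.5, min_depth: 10 }
    combin: { arrays: [13, 20, 13] }
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import collapse as collapse_mod
from . import combin as combin_mod
from . import kspec as kspec_mod
from . import overlaps as overlaps_mod
from .config import SimConfig
from .hetcall import analyze_genes
from .pileup import build_pileups
from .placement import place_readset
from .stats import assembly_stats
from .synth import (fragment_haplotypes, io as synth_io, paired_assembly,
                    simulate_diploid, simulate_fragments, simulate_reads,
                    simulate_transcripts, true_allelic_pairs)

ALL_STAGES = ("synth", "kspec", "collapse", "hetcall", "overlaps", "combin")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(outdir: Path, stage: str, message: str, echo=print) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(outdir / "pipeline.log", "a") as fh:
        fh.write(f"{stamp}\t{stage}\t{message}\n")
    echo(f"[{stage}] {message}")


def run_pipeline(config: dict, echo=print) -> dict:
    """Run the configured stages; returns the manifest dict."""
    outdir = Path(config.get("outdir", "hetkit_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    synth_cfg = dict(config.get("synth", {}))
    if "seed" in config:
        synth_cfg.setdefault("seed", int(config["seed"]))
    cfg = SimConfig.from_dict(synth_cfg)
    manifest: dict = {"config": config, "stages": []}

    def record(stage: str, params: dict, files: List[Path]) -> None:
        manifest["stages"].append({
            "stage": stage, "parameters": params,
            "outputs": {str(f.relative_to(outdir)): _sha256(f)
                        for f in files},
        })
        _log(outdir, stage, f"done ({len(files)} outputs)", echo)

    genome = reads = txset = fragset = None
    try:
        if "synth" in stages:
            d = outdir / "synth"
            d.mkdir(exist_ok=True)
            genome = simulate_diploid(cfg)
            reads = simulate_reads(genome, cfg)
            txset = simulate_transcripts(genome, cfg)
            fragset = simulate_fragments(genome, cfg)
            synth_io.write_fasta(genome.hapA, d / "hapA.fa")
            synth_io.write_fasta(genome.hapB, d / "hapB.fa")
            reads.write_fastq(d / "reads_R1.fq", d / "reads_R2.fq")
            txset.write_fasta(d / "transcripts.fa")
            txset.write_truth_tsv(d / "transcript_truth.tsv")
            synth_io.write_gff3(genome.genes, d / "genes.gff3")
            synth_io.write_vcf(genome, d / "variants.vcf")
            synth_io.write_repeats_bed(genome, d / "repeats.bed")
            synth_io.gene_truth_table(genome).to_csv(
                d / "gene_truth.tsv", sep="\t", index=False)
            fragset.write_fasta(d / "fragments.fa")
            record("synth", cfg.to_dict(), sorted(d.iterdir()))

        if "kspec" in stages:
            if reads is None:
                raise RuntimeError("kspec stage needs the synth stage")
            d = outdir / "kspec"
            d.mkdir(exist_ok=True)
            k = int(config.get("kspec", {}).get("k", 31))
            spectrum = kspec_mod.build_spectrum(reads, k)
            peaks = kspec_mod.detect_peaks(spectrum)
            size = kspec_mod.estimate_genome_size(spectrum, peaks)
            branches = kspec_mod.classify_branches(reads, k, peaks,
                                                   seed=cfg.seed)
            spectrum.write_tsv(d / "spectrum.tsv")
            with open(d / "peaks.json", "w") as fh:
                json.dump({**peaks.as_dict(),
                           "genome_size_estimate": size}, fh, indent=2)
            with open(d / "branches.json", "w") as fh:
                json.dump(branches.as_dict(), fh, indent=2)
            record("kspec", {"k": k}, sorted(d.iterdir()))

        if "collapse" in stages:
            if genome is None:
                raise RuntimeError("collapse stage needs the synth stage")
            d = outdir / "collapse"
            d.mkdir(exist_ok=True)
            pc = config.get("collapse", {})
            min_identity = float(pc.get("min_identity", 95.0))
            min_overlap = float(pc.get("min_overlap", 0.95))
            contigs = fragment_haplotypes(
                genome, cfg.seed, int(pc.get("piece_min", 5_000)),
                int(pc.get("piece_max", 20_000)))
            seqs = {c.name: c.seq for c in contigs}
            cands = collapse_mod.pairwise_similarity(seqs)
            mapping = collapse_mod.select_allelic_pairs(
                cands, {n: len(s) for n, s in seqs.items()},
                min_identity, min_overlap)
            result = collapse_mod.collapse(seqs, mapping,
                                           {"min_identity": min_identity,
                                            "min_overlap": min_overlap})
            pd.DataFrame([c.__dict__ for c in cands]).to_csv(
                d / "pairs.tsv", sep="\t", index=False)
            pd.DataFrame(result.to_rows(),
                         columns=["contig", "class", "primary"]).to_csv(
                d / "result.tsv", sep="\t", index=False)
            synth_io.write_fasta(result.primary, d / "primary.fa")
            truth_pairs = true_allelic_pairs(contigs)
            found = {frozenset((s, p)) for s, p in mapping.items()}
            stats = {
                "n_input": len(seqs),
                "n_primary": len(result.primary),
                "n_secondary": len(result.secondary),
                "primary": assembly_stats(
                    [len(s) for s in result.primary.values()]),
                "secondary": assembly_stats(
                    [len(s) for s in result.secondary.values()]),
                "truth_pairs": len(truth_pairs),
            }
            with open(d / "stats.json", "w") as fh:
                json.dump(stats, fh, indent=2)
            record("collapse", {"min_identity": min_identity,
                                "min_overlap": min_overlap},
                   sorted(d.iterdir()))

        if "hetcall" in stages:
            if genome is None or reads is None or txset is None:
                raise RuntimeError("hetcall stage needs the synth stage")
            d = outdir / "hetcall"
            d.mkdir(exist_ok=True)
            pc = config.get("hetcall", {})
            contigs, status = paired_assembly(
                genome, cfg.seed,
                split_rule=pc.get("split_rule", "density"),
                split_prob=float(pc.get("split_prob", 0.5)))
            placements = place_readset(reads, contigs, genome)
            piles = build_pileups(placements,
                                  {c.name: len(c.seq) for c in contigs})
            table, groups, _ = analyze_genes(
                txset.seqs, txset.gene_of,
                {c.name: c.seq for c in contigs}, piles,
                min_depth=int(pc.get("min_depth", 10)))
            table.to_csv(d / "gene_table.tsv", sep="\t", index=False)
            with open(d / "groups.json", "w") as fh:
                json.dump({"boundary": groups.boundary,
                           "upper": groups.upper,
                           "low_mode": groups.low_mode,
                           "high_mode": groups.high_mode,
                           "unimodal": groups.unimodal,
                           "true_status": status}, fh, indent=2)
            record("hetcall", pc, sorted(d.iterdir()))

        if "overlaps" in stages:
            if fragset is None:
                raise RuntimeError("overlaps stage needs the synth stage")
            d = outdir / "overlaps"
            d.mkdir(exist_ok=True)
            reports, het_records = overlaps_mod.analyze_fragment_set(
                fragset, genome, reads)
            pd.DataFrame([r.as_row() for r in reports]).to_csv(
                d / "overlap_reports.tsv", sep="\t", index=False)
            pd.DataFrame([r.__dict__ for r in het_records]).to_csv(
                d / "fragment_het.tsv", sep="\t", index=False)
            record("overlaps", {}, sorted(d.iterdir()))

        if "combin" in stages:
            d = outdir / "combin"
            d.mkdir(exist_ok=True)
            arrays = list(config.get("combin", {}).get("arrays",
                                                       [13, 20, 13]))
            n = combin_mod.count_combinations(arrays)
            with open(d / "combinations.json", "w") as fh:
                json.dump({"arrays": arrays, "combinations": n}, fh,
                          indent=2)
            record("combin", {"arrays": arrays}, sorted(d.iterdir()))
    except Exception as exc:
        manifest["failed_stage"] = _next_stage(manifest, stages)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(
            f"stage {manifest['failed_stage']!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _next_stage(manifest: dict, stages: List[str]) -> str:
    done = {s["stage"] for s in manifest["stages"]}
    for s in stages:
        if s not in done:
            return s
    return "unknown"


def summarize(outdir) -> dict:
    """Condense stage outputs into one machine- and human-readable summary."""
    outdir = Path(outdir)
    summary: dict = {"warnings": []}

    peaks_file = outdir / "kspec" / "peaks.json"
    if peaks_file.exists():
        summary["kspec"] = json.loads(peaks_file.read_text())
    else:
        summary["warnings"].append("kspec output missing")

    stats_file = outdir / "collapse" / "stats.json"
    if stats_file.exists():
        summary["collapse"] = json.loads(stats_file.read_text())
    else:
        summary["warnings"].append("collapse output missing")

    gene_file = outdir / "hetcall" / "gene_table.tsv"
    if gene_file.exists():
        table = pd.read_csv(gene_file, sep="\t")
        het = {}
        if len(table):
            for group, sub in table.groupby("group"):
                het[group] = {
                    "n_genes": int(len(sub)),
                    "mean_het_percent": float(sub["het_percent"].mean()),
                    "mean_popvar_percent":
                        float(sub["popvar_percent"].dropna().mean())
                        if sub["popvar_percent"].notna().any() else None,
                }
            split = het.get("split", {}).get("mean_het_percent")
            merged = het.get("merged", {}).get("mean_het_percent")
            summary["hetcall"] = {
                "groups": het,
                "split_exceeds_merged":
                    (split is not None and merged is not None
                     and split > merged),
            }
        else:
            summary["hetcall"] = {"groups": {},
                                  "split_exceeds_merged": None}
            summary["warnings"].append("het table empty: group means absent")
    else:
        summary["warnings"].append("hetcall output missing")

    ov_file = outdir / "overlaps" / "overlap_reports.tsv"
    if ov_file.exists():
        ov = pd.read_csv(ov_file, sep="\t")
        summary["overlaps"] = {
            "n_pairs": int(len(ov)),
            "total_snps_pairwise": int(ov["snps_pairwise"].sum()),
            "total_indels": int(ov["n_indels"].sum()),
            "total_indels_ge_100": int(ov["n_indels_ge_100"].sum()),
        }
    comb_file = outdir / "combin" / "combinations.json"
    if comb_file.exists():
        summary["combin"] = json.loads(comb_file.read_text())

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    lines = [f"hetkit pipeline summary: {outdir}"]
    for key, value in summary.items():
        if key == "warnings":
            continue
        lines.append(f"  {key}: {json.dumps(value)}")
    for w in summary["warnings"]:
        lines.append(f"  WARNING: {w}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
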