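"""Long contiguous fragments (BAC-like) tiling one chromosome.

Fragments form a tiling path with a fixed declared overlap in ancestral
(hapA) coordinates; each fragment is drawn from a single randomly chosen
haplotype, as expected for clones made from pooled animals. The declared
truth for each consecutive pair lists every planted variant that falls in
the overlap and distinguishes the two haplotypes — empty when both
fragments happen to come from the same haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import bisect

import numpy as np

from ..config import ConfigError, SimConfig
from ..coords import Variant
from .genome import DiploidGenome


def _indel_footprints(variants) -> List[Tuple[int, int]]:
    """Merged exclusion zones around planted indels (with 1 bp guards)."""
    raw = []
    for v in variants:
        if v.kind == "del":
            raw.append((v.pos - 1, v.pos + len(v.ref) + 1))
        elif v.kind == "ins":
            raw.append((v.pos - 1, v.pos + 2))
    raw.sort()
    merged: List[Tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _snap(pos: int, fps: List[Tuple[int, int]], direction: int, L: int) -> int:
    """Move ``pos`` out of any indel footprint (left if direction<0)."""
    starts = [s for s, _ in fps]
    while True:
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and fps[i][0] <= pos < fps[i][1]:
            pos = fps[i][0] - 1 if direction < 0 else fps[i][1]
        else:
            break
    return min(max(pos, 0), L)


@dataclass(frozen=True)
class Fragment:
    name: str
    chrom: str
    hap: str                 # "A" | "B"
    a_start: int             # ancestral (hapA) interval
    a_end: int
    start: int               # interval on the source haplotype
    end: int
    seq: str


@dataclass(frozen=True)
class OverlapTruth:
    """Planted differences inside the overlap of a consecutive pair."""

    name_a: str
    name_b: str
    a_lo: int                # ancestral overlap interval
    a_hi: int
    same_hap: bool
    snps: Tuple[Variant, ...]
    indels: Tuple[Variant, ...]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    def n_indels_ge(self, min_len: int = 100) -> int:
        return sum(1 for v in self.indels if v.length >= min_len)


@dataclass
class FragmentSet:
    fragments: List[Fragment]
    overlaps: List[OverlapTruth]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for fr in self.fragments:
                fh.write(f">{fr.name} chrom={fr.chrom} hap={fr.hap} "
                         f"a_start={fr.a_start} a_end={fr.a_end}\n")
                for i in range(0, len(fr.seq), 80):
                    fh.write(fr.seq[i:i + 80] + "\n")


def simulate_fragments(genome: DiploidGenome, cfg: SimConfig) -> FragmentSet:
    """Tile the longest chromosome with single-haplotype fragments."""
    if cfg.fragment_overlap >= cfg.fragment_len:
        raise ConfigError("fragment_overlap must be below fragment_len")
    chrom = max(genome.hapA, key=lambda c: len(genome.hapA[c]))
    L = len(genome.hapA[chrom])
    if cfg.fragment_len > L:
        raise ConfigError("fragment_len exceeds chromosome length")
    step = cfg.fragment_len - cfg.fragment_overlap
    span = step * (cfg.n_fragments - 1) + cfg.fragment_len
    if span > L:
        raise ConfigError(
            f"{cfg.n_fragments} fragments of {cfg.fragment_len} bp with "
            f"{cfg.fragment_overlap} bp overlap need {span} bp, have {L}")
    rng = np.random.default_rng([cfg.seed, 3])
    cmap = genome.coord_maps[chrom]
    variants = genome.variants[chrom]

    # fragment ends are nudged out of indel footprints so that overlap
    # truth is unambiguous (no planted event straddles a boundary)
    fps = _indel_footprints(variants)
    frags: List[Fragment] = []
    for i in range(cfg.n_fragments):
        a0 = _snap(i * step, fps, -1, L)
        a1 = _snap(i * step + cfg.fragment_len, fps, +1, L)
        hap = "A" if rng.random() < 0.5 else "B"
        if hap == "A":
            s, e = a0, a1
            seq = genome.hapA[chrom][s:e]
        else:
            s, e = cmap.interval_a_to_b(a0, a1)
            seq = genome.hapB[chrom][s:e]
        frags.append(Fragment(f"frag{i:03d}", chrom, hap, a0, a1, s, e, seq))

    overlaps: List[OverlapTruth] = []
    for fa, fb in zip(frags, frags[1:]):
        lo, hi = fb.a_start, fa.a_end
        same = fa.hap == fb.hap
        if same:
            snps: Tuple[Variant, ...] = ()
            indels: Tuple[Variant, ...] = ()
        else:
            inside = [v for v in variants if lo <= v.pos < hi]
            snps = tuple(v for v in inside if v.kind == "snp")
            indels = tuple(v for v in inside if v.is_indel)
        overlaps.append(OverlapTruth(fa.name, fb.name, lo, hi, same,
                                     snps, indels))
    return FragmentSet(frags, overlaps)
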