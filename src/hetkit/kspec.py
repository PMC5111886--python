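"""K-mer spectrum diagnostics for heterozygosity and repeat content.

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement) are counted exactly, streaming reads in chunks into one packed
uint64 array that is sorted in place — no probabilistic sketches. On a
diploid read set the multiplicity histogram is bimodal: k-mers spanning a
heterozygous site occur on one haplotype only and peak at half the
coverage of the homozygous peak. Peak positions drive the error cutoff,
a haploid genome-size estimate, and coverage thresholds used to classify
de-Bruijn branchings into variant-like and repeat-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import dna
from .synth.reads import ReadSet

_CHUNK = 200_000  # reads per packing chunk


class SpectrumError(ValueError):
    pass


# ---------------------------------------------------------------------------
# packing


def _validate_k(k: int) -> None:
    # analysis-scale k is 15..63; tiny odd k stays legal for hand-checkable
    # examples and oracle tests
    if k % 2 == 0 or not 3 <= k <= 63:
        raise SpectrumError(f"k must be odd and in [3, 63], got {k}")


def _pack_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mers of every row of an (n, L) code matrix, flattened."""
    n, L = codes.shape
    if L < k:
        raise SpectrumError(f"reads shorter than k={k}")
    w = L - k + 1
    mat = codes.astype(np.uint64)
    comp = np.uint64(3) - mat
    fwd = np.zeros((n, w), dtype=np.uint64)
    rev = np.zeros((n, w), dtype=np.uint64)
    for j in range(k):
        fwd <<= np.uint64(2)
        fwd |= mat[:, j:j + w]
        rev |= comp[:, j:j + w] << np.uint64(2 * j)
    np.minimum(fwd, rev, out=fwd)
    return fwd.ravel()


def _iter_code_chunks(reads: Union[ReadSet, Sequence[str], np.ndarray]
                      ) -> Iterable[np.ndarray]:
    if isinstance(reads, ReadSet):
        for mat in (reads.r1, reads.r2):
            for i in range(0, mat.shape[0], _CHUNK):
                yield mat[i:i + _CHUNK]
    elif isinstance(reads, np.ndarray):
        for i in range(0, reads.shape[0], _CHUNK):
            yield reads[i:i + _CHUNK]
    else:  # sequence of strings; group by equal length for matrix packing
        by_len: Dict[int, List[np.ndarray]] = {}
        for s in reads:
            by_len.setdefault(len(s), []).append(dna.encode(s))
        for ln, rows in by_len.items():
            mat = np.vstack(rows)
            for i in range(0, mat.shape[0], _CHUNK):
                yield mat[i:i + _CHUNK]


def count_kmers(reads, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Exact canonical k-mer counting.

    Returns ``(kmers, counts)`` with ``kmers`` sorted ascending.
    """
    _validate_k(k)
    chunks = [_pack_matrix(c, k) for c in _iter_code_chunks(reads)]
    if not chunks:
        raise SpectrumError("no reads")
    packed = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    del chunks
    packed.sort(kind="stable")
    boundary = np.empty(packed.size, dtype=bool)
    boundary[0] = True
    np.not_equal(packed[1:], packed[:-1], out=boundary[1:])
    starts = np.flatnonzero(boundary)
    counts = np.diff(np.append(starts, packed.size))
    return packed[starts], counts


# ---------------------------------------------------------------------------
# spectrum


@dataclass
class KmerSpectrum:
    """Multiplicity histogram of distinct canonical k-mers."""

    k: int
    hist: np.ndarray           # hist[m] = number of distinct k-mers seen m times

    @property
    def total_kmers(self) -> int:
        return int((np.arange(len(self.hist)) * self.hist).sum())

    @property
    def n_distinct(self) -> int:
        return int(self.hist.sum())

    def as_dict(self) -> Dict[int, int]:
        return {m: int(c) for m, c in enumerate(self.hist) if c > 0}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tcount\n")
            for m, c in self.as_dict().items():
                fh.write(f"{m}\t{c}\n")

    @classmethod
    def read_tsv(cls, path, k: int) -> "KmerSpectrum":
        ms, cs = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                m, c = line.split("\t")
                ms.append(int(m))
                cs.append(int(c))
        hist = np.zeros(max(ms) + 1, dtype=np.int64)
        hist[ms] = cs
        return cls(k, hist)


def build_spectrum(reads, k: int = 31) -> KmerSpectrum:
    """K-mer multiplicity spectrum of a read set (exact, canonical)."""
    _, counts = count_kmers(reads, k)
    hist = np.bincount(counts)
    return KmerSpectrum(k, hist.astype(np.int64))


# ---------------------------------------------------------------------------
# peak detection


@dataclass
class SpectrumPeaks:
    error_cutoff: int
    hom_peak: int
    het_peak: Optional[int] = None

    @property
    def peak_ratio(self) -> Optional[float]:
        if self.het_peak is None:
            return None
        return self.het_peak / self.hom_peak

    def as_dict(self) -> dict:
        return {"error_cutoff": self.error_cutoff, "het_peak": self.het_peak,
                "hom_peak": self.hom_peak, "peak_ratio": self.peak_ratio}


def _smooth(hist: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(hist.astype(float), kernel, mode="same")


def detect_peaks(spectrum: KmerSpectrum, smooth_window: int = 3,
                 min_separation: float = 1.5,
                 min_rel_height: float = 0.05) -> SpectrumPeaks:
    """Locate the error cutoff and the het/hom coverage peaks.

    The error cutoff is the first local minimum of the raw histogram above
    multiplicity 0 (the error tail decays; the first non-decreasing bin
    marks its end); the two highest smoothed local maxima above it whose
    multiplicities differ by at least ``min_separation``-fold are reported,
    the larger multiplicity being the homozygous peak. A unimodal spectrum
    yields a homozygous peak with the het peak flagged absent.
    """
    hist = spectrum.hist
    if len(hist) < 4 or spectrum.n_distinct == 0:
        raise SpectrumError("spectrum is degenerate")
    sm = _smooth(hist, smooth_window)
    cutoff = None
    for m in range(1, len(hist) - 1):
        if hist[m] <= hist[m + 1]:
            cutoff = m
            break
    if cutoff is None:
        raise SpectrumError("monotonically decreasing spectrum: no peaks")
    interior = np.arange(cutoff + 1, len(sm) - 1)
    is_max = (sm[interior] >= sm[interior - 1]) & (sm[interior] > sm[interior + 1])
    maxima = interior[is_max]
    if maxima.size == 0:
        raise SpectrumError("no local maxima above the error cutoff")
    order = maxima[np.argsort(sm[maxima])[::-1]]
    first = int(order[0])
    second = None
    for cand in order[1:]:
        if sm[cand] < min_rel_height * sm[first]:
            break  # remaining maxima are noise-level
        ratio = max(cand, first) / min(cand, first)
        if ratio >= min_separation:
            second = int(cand)
            break
    if second is None:
        return SpectrumPeaks(cutoff, hom_peak=first, het_peak=None)
    hom, het = max(first, second), min(first, second)
    return SpectrumPeaks(cutoff, hom_peak=hom, het_peak=het)


def estimate_genome_size(spectrum: KmerSpectrum, peaks: SpectrumPeaks) -> float:
    """Haploid genome size: above-cutoff k-mer mass over the homozygous peak.

    Heterozygous k-mers sit at half the homozygous multiplicity, so their
    mass contributes each het locus once per haplotype automatically.
    """
    if peaks.hom_peak is None:
        raise SpectrumError("homozygous peak required")
    m = np.arange(len(spectrum.hist))
    mask = m > peaks.error_cutoff
    mass = float((m[mask] * spectrum.hist[mask]).sum())
    return mass / peaks.hom_peak


# ---------------------------------------------------------------------------
# cross-library intersection


def intersect_kmers(reads_a, reads_b, k: int = 31,
                    error_cutoff: Optional[int] = None) -> float:
    """Jaccard fraction of distinct above-error k-mers shared by two sets."""
    uniq = []
    for reads in (reads_a, reads_b):
        kmers, counts = count_kmers(reads, k)
        if kmers.size == 0:
            raise SpectrumError("empty read set")
        cut = error_cutoff
        if cut is None:
            spec = KmerSpectrum(k, np.bincount(counts).astype(np.int64))
            try:
                cut = detect_peaks(spec).error_cutoff
            except SpectrumError:
                cut = 0
        uniq.append(kmers[counts > cut])
    inter = np.intersect1d(uniq[0], uniq[1], assume_unique=True).size
    union = uniq[0].size + uniq[1].size - inter
    if union == 0:
        raise SpectrumError("no k-mers above the error cutoff")
    return inter / union


# ---------------------------------------------------------------------------
# de-Bruijn branch classification


@dataclass
class BranchStats:
    sampled_kmers: int
    variant_branch_rate: float
    repeat_branch_rate: float
    het_peak_available: bool = True

    def as_dict(self) -> dict:
        return {"sampled_kmers": self.sampled_kmers,
                "variant_branch_rate": self.variant_branch_rate,
                "repeat_branch_rate": self.repeat_branch_rate,
                "het_peak_available": self.het_peak_available}


def _revcomp_packed(x: np.ndarray, k: int) -> np.ndarray:
    x = x ^ np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x & np.uint64(0x3333333333333333)) << np.uint64(2)) | \
        ((x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = ((x & np.uint64(0x0F0F0F0F0F0F0F0F)) << np.uint64(4)) | \
        ((x >> np.uint64(4)) & np.uint64(0x0F0F0F0F0F0F0F0F))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def classify_branches(reads, k: int, peaks: SpectrumPeaks,
                      max_sample: int = 100_000, seed: int = 0,
                      variant_factor: float = 1.5,
                      repeat_factor: float = 1.75,
                      counted: Optional[Tuple[np.ndarray, np.ndarray]] = None
                      ) -> BranchStats:
    """Sample above-error k-mers and rate their graph branchings.

    For each sampled k-mer and each strand direction, extensions are the
    four possible next bases whose extension k-mer multiplicity exceeds the
    error cutoff. Exactly two extensions with both multiplicities at most
    ``variant_factor`` x het peak is a variant-like branch (balanced
    haplotype bubble); three or more extensions, or any extension above
    ``repeat_factor`` x hom peak, is repeat-like.
    """
    kmers, counts = counted if counted is not None else count_kmers(reads, k)
    cut = peaks.error_cutoff
    solid = counts > cut
    pool = np.flatnonzero(solid)
    rng = np.random.default_rng(seed)
    if pool.size > max_sample:
        pool = rng.choice(pool, size=max_sample, replace=False)
        pool.sort()
    sample = kmers[pool]
    het_available = peaks.het_peak is not None
    mask = np.uint64((1 << (2 * k)) - 1)

    def lookup(vals: np.ndarray) -> np.ndarray:
        canon = np.minimum(vals, _revcomp_packed(vals, k))
        idx = np.searchsorted(kmers, canon)
        idx = np.clip(idx, 0, kmers.size - 1)
        hit = kmers[idx] == canon
        out = np.where(hit, counts[idx], 0)
        return out

    variant = np.zeros(sample.size, dtype=np.int64)
    repeat = np.zeros(sample.size, dtype=np.int64)
    for direction in ("fwd", "rc"):
        base_val = sample if direction == "fwd" else _revcomp_packed(sample, k)
        ext_counts = np.zeros((4, sample.size), dtype=np.int64)
        for b in range(4):
            ext = ((base_val << np.uint64(2)) | np.uint64(b)) & mask
            ext_counts[b] = lookup(ext)
        above = ext_counts > cut
        n_ext = above.sum(axis=0)
        max_ext = ext_counts.max(axis=0)
        rep = (n_ext >= 3) | (max_ext > repeat_factor * peaks.hom_peak)
        repeat += rep
        if het_available:
            two = n_ext == 2
            within = np.where(above, ext_counts,
                              0).max(axis=0) <= variant_factor * peaks.het_peak
            variant += two & within & ~rep
    n = int(sample.size)
    if n == 0:
        raise SpectrumError("no solid k-mers to sample")
    return BranchStats(n, float(variant.sum()) / n, float(repeat.sum()) / n,
                       het_peak_available=het_available)
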