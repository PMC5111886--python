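"""Allelic-contig discovery and assembly collapse.

In a highly heterozygous assembly many regions assemble twice, once per
haplotype. Candidate allelic pairs are found by shared-k-mer seeding
followed by banded edit-distance alignment of the implied overlapping
windows; pairs above identity and overlap-fraction cutoffs are clustered,
the longest contig of each cluster is kept as primary for scaffolding, and
the shorter allelic contigs are set aside to be added back afterwards.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import edlib
import numpy as np

from . import dna
from .stats import assembly_stats

SEED_K = 21


class CollapseError(ValueError):
    pass


@dataclass(frozen=True)
class CandidatePair:
    """An unordered contig pair with alignment statistics."""

    a: str
    b: str
    identity: float        # percent (convention set by gap_policy)
    aln_len: int           # alignment columns
    overlap_frac: float    # aligned span / length of the shorter contig


@dataclass
class CollapseResult:
    primary: Dict[str, str]
    secondary: Dict[str, str]
    mapping: Dict[str, str]          # secondary -> primary
    params: Dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> List[Tuple[str, str, str]]:
        rows = [(name, "primary", "") for name in sorted(self.primary)]
        rows += [(name, "secondary", self.mapping[name])
                 for name in sorted(self.secondary)]
        return rows


# ---------------------------------------------------------------------------
# candidate discovery


def _contig_kmers(seq: str, k: int = SEED_K) -> Tuple[np.ndarray, np.ndarray]:
    """Sorted unique canonical k-mers and representative positions."""
    codes = dna.encode(seq)[None, :]
    w = len(seq) - k + 1
    if w <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    fwd = np.zeros((1, w), dtype=np.uint64)
    rev = np.zeros((1, w), dtype=np.uint64)
    for j in range(k):
        col = codes[:, j:j + w].astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | col
        rev |= (np.uint64(3) - col) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev).ravel()
    order = np.argsort(canon, kind="stable")
    canon_sorted = canon[order]
    keep = np.concatenate(([True], canon_sorted[1:] != canon_sorted[:-1]))
    # positions of k-mers occurring exactly once (reliable anchors)
    runs = np.flatnonzero(keep)
    run_len = np.diff(np.append(runs, canon.size))
    uniq_mask = run_len == 1
    return canon_sorted[keep], np.where(uniq_mask, order[runs], -1)


def _pair_alignment(seq_a: str, seq_b: str,
                    km_a, km_b, margin: int = 200,
                    gap_policy: str = "exclude"
                    ) -> Optional[CandidatePair]:
    kmers_a, pos_a = km_a
    kmers_b, pos_b = km_b
    common, ia, ib = np.intersect1d(kmers_a, kmers_b, assume_unique=True,
                                    return_indices=True)
    if common.size == 0:
        return None
    pa, pb = pos_a[ia], pos_b[ib]
    anchors = (pa >= 0) & (pb >= 0)
    if anchors.sum() == 0:
        return None
    offset = int(np.median(pa[anchors] - pb[anchors]))
    # implied overlap window: exact on the query (b), margin on the target
    # (a) so edlib can slide the infix alignment to the true boundary
    a_lo = max(0, max(0, offset) - margin)
    a_hi = min(len(seq_a), min(len(seq_a), offset + len(seq_b)) + margin)
    b_lo = max(0, -offset)
    b_hi = min(len(seq_b), len(seq_a) - offset)
    if a_hi - a_lo < SEED_K or b_hi - b_lo < SEED_K:
        return None
    query = seq_b[b_lo:b_hi]
    target = seq_a[a_lo:a_hi]
    # banded distance first: pairs far below any reportable identity
    # (shared repeat copies between unrelated contigs) abort cheaply
    cap = max(int(0.35 * len(query)), 50)
    if edlib.align(query, target, mode="HW", k=cap)["editDistance"] < 0:
        return None
    res = edlib.align(query, target, mode="HW", task="path", k=cap)
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    matches = cols = pairs = 0
    for ln, op in _iter_cigar(res["cigar"]):
        cols += ln
        if op in ("=", "X"):
            pairs += ln
        if op == "=":
            matches += ln
    if gap_policy == "mismatch":
        identity = 100.0 * matches / cols if cols else 0.0
    else:  # "exclude": identity over aligned base pairs, gaps apart
        identity = 100.0 * matches / pairs if pairs else 0.0
    overlap = cols / min(len(seq_a), len(seq_b))
    return CandidatePair("", "", identity, cols, min(overlap, 1.0))


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def pairwise_similarity(contigs: Dict[str, str], min_seed_matches: int = 10,
                        seed_k: int = SEED_K,
                        gap_policy: str = "exclude") -> List[CandidatePair]:
    """All-vs-all candidate alignment, seeded by shared canonical k-mers.

    ``gap_policy`` sets the identity convention: "exclude" (default)
    reports matches over aligned base pairs with gap columns kept out of
    the identity (so a single long indel does not mask an otherwise
    near-identical allelic pair), "mismatch" counts gap columns as
    mismatches.
    """
    names = list(contigs)
    if len(names) != len(set(names)) or len(names) < 2:
        raise CollapseError("need >= 2 uniquely named contigs")
    km = {n: _contig_kmers(contigs[n], seed_k) for n in names}
    out: List[CandidatePair] = []
    for na, nb in itertools.combinations(sorted(names), 2):
        shared = np.intersect1d(km[na][0], km[nb][0], assume_unique=True).size
        if shared < min_seed_matches:
            continue
        pair = _pair_alignment(contigs[na], contigs[nb], km[na], km[nb],
                               gap_policy=gap_policy)
        if pair is not None:
            out.append(CandidatePair(na, nb, pair.identity, pair.aln_len,
                                     pair.overlap_frac))
    return out


# ---------------------------------------------------------------------------
# selection and collapse


def select_allelic_pairs(candidates: Sequence[CandidatePair],
                         lengths: Dict[str, int],
                         min_identity: float = 95.0,
                         min_overlap: float = 0.95,
                         inclusive: bool = False) -> Dict[str, str]:
    """Resolve passing candidates into a secondary -> primary mapping.

    Thresholds are strict (>) by default. Multi-way clusters (connected
    components of passing pairs) resolve to a single primary: the longest
    contig, ties broken by lexicographically smaller name.
    """
    if inclusive:
        passing = [c for c in candidates if c.identity >= min_identity
                   and c.overlap_frac >= min_overlap]
    else:
        passing = [c for c in candidates if c.identity > min_identity
                   and c.overlap_frac > min_overlap]
    parent: Dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for c in passing:
        for n in (c.a, c.b):
            parent.setdefault(n, n)
        ra, rb = find(c.a), find(c.b)
        if ra != rb:
            parent[rb] = ra
    clusters: Dict[str, List[str]] = {}
    for n in parent:
        clusters.setdefault(find(n), []).append(n)
    mapping: Dict[str, str] = {}
    for members in clusters.values():
        members.sort(key=lambda n: (-lengths[n], n))
        primary = members[0]
        for sec in members[1:]:
            mapping[sec] = primary
    return mapping


def collapse(contigs: Dict[str, str], mapping: Dict[str, str],
             params: Optional[Dict[str, float]] = None) -> CollapseResult:
    """Partition contigs into primary and secondary sets."""
    for sec, pri in mapping.items():
        if sec not in contigs or pri not in contigs:
            raise CollapseError(f"mapping references unknown contig "
                                f"{sec!r} or {pri!r}")
        if len(contigs[pri]) < len(contigs[sec]):
            raise CollapseError(f"primary {pri!r} shorter than secondary "
                                f"{sec!r}")
    secondary = {n: contigs[n] for n in mapping}
    primary = {n: s for n, s in contigs.items() if n not in mapping}
    return CollapseResult(primary, secondary, dict(mapping),
                          dict(params or {}))


def reintegrate(scaffolds: Dict[str, Sequence[str]],
                scaffold_seqs: Dict[str, str],
                result: CollapseResult) -> Dict[str, dict]:
    """Assemble the final record classes and their length statistics.

    ``scaffolds`` maps scaffold name -> primary contigs it contains;
    primaries in no scaffold are "unplaced", collapsed allelic contigs come
    back as "heterozygous". Returns per-class stats (n, N90/N50/N10, sum,
    max) in the shape of a standard assembly summary table.
    """
    placed: Set[str] = set()
    for name, members in scaffolds.items():
        for m in members:
            if m not in result.primary:
                raise CollapseError(f"scaffold {name!r} references unknown "
                                    f"primary {m!r}")
            if m in placed:
                raise CollapseError(f"primary {m!r} in more than one scaffold")
            placed.add(m)
    unplaced = {n: s for n, s in result.primary.items() if n not in placed}
    classes = {
        "scaffolds": [len(s) for s in scaffold_seqs.values()],
        "unplaced_contigs": [len(s) for s in unplaced.values()],
        "heterozygous_contigs": [len(s) for s in result.secondary.values()],
    }
    return {cls: assembly_stats(lens) for cls, lens in classes.items()}
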