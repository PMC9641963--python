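"""Segmental-duplication post-processing.

Takes a table of pairwise self-alignments (one row per duplication pair, the
unit a whole-genome self-aligner emits), removes pairs dominated by common
repeats, builds the transitive-copy interval graph, drops high-copy repeat
families, and summarizes the retained duplication landscape. A desk-scale
self-aligner is included as plumbing so the stage is exercisable on synthetic
genomes; production runs consume an external self-alignment table.

The copy-number graph follows the interval-graph construction: every repeated
interval is a node; edges join the two intervals of each alignment pair and
any two intervals that overlap on the same scaffold; the number of unique
(exact-coordinate) intervals in a connected component is that repeat's copy
number.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .regions import GenomicInterval, build_track, covered_fraction, total_bases
from .synthetic import SyntheticGenome


@dataclass(frozen=True)
class DuplicationPair:
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    identity: float
    length: int
    masked_frac_a: float = 0.0
    masked_frac_b: float = 0.0

    def __post_init__(self):
        if self.interval_a.length <= 0 or self.interval_b.length <= 0:
            raise ValueError("degenerate interval in duplication pair")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.length <= 0:
            raise ValueError("alignment length must be > 0")


@dataclass
class DuplicationComponent:
    intervals: set[GenomicInterval]
    copy_number: int
    edges: list[tuple[GenomicInterval, GenomicInterval, str]] = field(default_factory=list)


@dataclass
class SDConfig:
    masked_threshold: float = 0.90
    max_copies: int = 20
    min_length: int = 1_000
    min_identity: float = 0.90
    divergence_per_100ky: float = 0.005
    generations_per_year: float = 3.0

    def __post_init__(self):
        if not (0 < self.masked_threshold <= 1):
            raise ValueError("masked_threshold must be in (0, 1]")
        if self.max_copies < 2:
            raise ValueError("max_copies must be >= 2")


@dataclass
class SDSummary:
    n_pairs: int
    nonredundant_bases: int
    identity_bins: np.ndarray
    identity_histogram: np.ndarray


MAX_SELF_ALIGN_BP = 10_000_000


def _canonical(pair: DuplicationPair) -> DuplicationPair:
    a, b = pair.interval_a, pair.interval_b
    if (a.scaffold, a.start, a.end) > (b.scaffold, b.start, b.end):
        return replace(pair, interval_a=b, interval_b=a,
                       masked_frac_a=pair.masked_frac_b, masked_frac_b=pair.masked_frac_a)
    return pair


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """(matched-bases / aligned-columns, columns) from an extended cigar."""
    num = ""
    matches = cols = 0
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return (matches / cols if cols else 0.0), cols


def alignment_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Global-alignment identity (matched bases over aligned columns)."""
    res = edlib.align(seq_a, seq_b, task="path", mode="NW")
    return _cigar_identity(res["cigar"])


def naive_self_align(
    genome: SyntheticGenome,
    min_length: int = 1_000,
    min_identity: float = 0.90,
    k: int = 20,
    max_kmer_hits: int = 50,
    band: int = 200,
) -> list[DuplicationPair]:
    """Desk-scale self-alignment by exact k-mer anchoring plus gapped refinement.

    Seeds are shared k-mers (forward strand only); anchors on a common
    off-diagonal are clustered into candidate interval pairs, each of which is
    refined by a full edit-distance alignment to produce identity over aligned
    columns. Refuses genomes above ~10 Mb, where an external aligner should
    produce the pair table instead.
    """
    genome_bp = sum(len(s) for s in genome.sequences.values())
    if genome_bp > MAX_SELF_ALIGN_BP:
        raise ValueError(
            f"genome of {genome_bp} bp exceeds the {MAX_SELF_ALIGN_BP} bp naive-alignment "
            "limit; provide an external self-alignment table instead"
        )

    # global coordinates to simplify cross-scaffold anchoring
    names = list(genome.sequences)
    offsets: dict[str, int] = {}
    pos = 0
    blob_parts = []
    for name in names:
        offsets[name] = pos
        blob_parts.append(genome.sequences[name])
        pos += len(genome.sequences[name]) + 1  # separator breaks k-mers
    blob = "\x00".join(blob_parts)
    bounds = sorted((off, off + len(genome.sequences[n]), n) for n, off in offsets.items())

    def locate(gpos: int) -> tuple[str, int]:
        for s, e, n in bounds:
            if s <= gpos < e:
                return n, gpos - s
        raise IndexError(gpos)

    # vectorized k-mer integer codes (2 bits per base, k <= 31)
    lut = np.full(256, -1, dtype=np.int64)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    arr = lut[np.frombuffer(blob.encode("ascii", "replace"), dtype=np.uint8)]
    n_codes = len(arr) - k + 1
    codes = np.zeros(n_codes, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | arr[j:j + n_codes]
    bad = np.cumsum(np.concatenate(([0], (arr < 0).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    positions_all = np.nonzero(valid)[0]
    order = positions_all[np.argsort(codes[positions_all], kind="stable")]
    sorted_codes = codes[order]
    run_starts = np.nonzero(np.diff(sorted_codes, prepend=sorted_codes[0] - 1))[0] \
        if len(sorted_codes) else np.array([], dtype=int)

    # anchors grouped by off-diagonal
    by_diag: dict[int, list[int]] = {}
    run_bounds = list(run_starts) + [len(sorted_codes)]
    for ri in range(len(run_bounds) - 1):
        lo_i, hi_i = run_bounds[ri], run_bounds[ri + 1]
        count = hi_i - lo_i
        if count < 2 or count > max_kmer_hits:
            continue
        positions = sorted(int(p) for p in order[lo_i:hi_i])
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                p1, p2 = positions[ai], positions[bi]
                by_diag.setdefault(p2 - p1, []).append(p1)

    # merge nearby diagonals, then chain anchors along each diagonal band
    candidates: list[tuple[int, int, int, int]] = []  # (a0, a1, b0, b1) global
    diags = sorted(by_diag)
    grouped: list[list[int]] = []
    group_anchors: list[list[tuple[int, int]]] = []
    for d in diags:
        if grouped and d - grouped[-1][-1] <= band:
            grouped[-1].append(d)
            group_anchors[-1].extend((p, d) for p in by_diag[d])
        else:
            grouped.append([d])
            group_anchors.append([(p, d) for p in by_diag[d]])
    for anchors in group_anchors:
        anchors.sort()
        chain: list[tuple[int, int]] = []
        for p, d in anchors:
            if chain and p - chain[-1][0] > max(2_000, band * 5):
                candidates.append(_chain_bounds(chain, k))
                chain = []
            chain.append((p, d))
        if chain:
            candidates.append(_chain_bounds(chain, k))

    pairs: list[DuplicationPair] = []
    for a0, a1, b0, b1 in candidates:
        if min(a1 - a0, b1 - b0) < max(min_length // 2, k):
            continue
        if a1 > b0:  # candidate halves touch (tandem) or overlap (self-match)
            if a1 - b0 > band:
                continue
            mid = (a1 + b0) // 2  # trim the stray-anchor fringe at the junction
            a1, b0 = mid, mid
        try:
            scaf_a, ra0 = locate(a0)
            scaf_a_end, ra1 = locate(a1 - 1)
            scaf_b, rb0 = locate(b0)
            scaf_b_end, rb1 = locate(b1 - 1)
        except IndexError:
            continue
        if scaf_a != scaf_a_end or scaf_b != scaf_b_end:
            continue
        seq_a = genome.sequences[scaf_a][ra0:ra1 + 1]
        seq_b = genome.sequences[scaf_b][rb0:rb1 + 1]
        ident, cols = alignment_identity(seq_a, seq_b)
        if cols < min_length or ident < min_identity:
            continue
        pairs.append(_canonical(DuplicationPair(
            interval_a=GenomicInterval(scaf_a, ra0, ra1 + 1),
            interval_b=GenomicInterval(scaf_b, rb0, rb1 + 1),
            identity=ident,
            length=cols,
        )))
    return _dedupe_pairs(pairs)


def _chain_bounds(chain: list[tuple[int, int]], k: int) -> tuple[int, int, int, int]:
    a0 = min(p for p, _ in chain)
    a1 = max(p for p, _ in chain) + k
    b0 = min(p + d for p, d in chain)
    b1 = max(p + d for p, d in chain) + k
    return a0, a1, b0, b1


def _jaccard(x: GenomicInterval, y: GenomicInterval) -> float:
    if x.scaffold != y.scaffold:
        return 0.0
    inter = max(0, min(x.end, y.end) - max(x.start, y.start))
    union = max(x.end, y.end) - min(x.start, y.start)
    return inter / union if union else 0.0


def _dedupe_pairs(pairs: list[DuplicationPair]) -> list[DuplicationPair]:
    """Collapse near-duplicate pair reports (both intervals >=80% reciprocal)."""
    kept: list[DuplicationPair] = []
    for pair in sorted(pairs, key=lambda p: -p.length):
        redundant = any(
            _jaccard(pair.interval_a, q.interval_a) > 0.8
            and _jaccard(pair.interval_b, q.interval_b) > 0.8
            for q in kept
        )
        if not redundant:
            kept.append(pair)
    kept.sort(key=lambda p: (p.interval_a.scaffold, p.interval_a.start,
                             p.interval_b.scaffold, p.interval_b.start))
    return kept


def filter_repeat_masked(
    pairs: list[DuplicationPair],
    repeat_track: list[GenomicInterval],
    cfg: SDConfig | None = None,
) -> list[DuplicationPair]:
    """Drop pairs in which either copy is over ``masked_threshold`` repeat-masked.

    Masked fraction is computed against the union of the repeat intervals.
    Retained pairs carry their computed masked fractions; order is preserved.
    """
    cfg = cfg or SDConfig()
    track = build_track(repeat_track)
    out = []
    for pair in pairs:
        fa = covered_fraction(pair.interval_a, track)
        fb = covered_fraction(pair.interval_b, track)
        if fa <= cfg.masked_threshold and fb <= cfg.masked_threshold:
            out.append(replace(pair, masked_frac_a=fa, masked_frac_b=fb))
    return out


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def build_duplication_graph(pairs: list[DuplicationPair]) -> list[DuplicationComponent]:
    """Connected components over alignment edges plus >=1 bp overlap edges.

    Nodes are the distinct (exact-coordinate) intervals appearing in the
    pairs; the copy number of a component is its number of unique intervals,
    capturing transitive copies a pairwise aligner may have missed.
    """
    nodes: set[GenomicInterval] = set()
    edges: list[tuple[GenomicInterval, GenomicInterval, str]] = []
    for pair in pairs:
        nodes.add(pair.interval_a)
        nodes.add(pair.interval_b)
        edges.append((pair.interval_a, pair.interval_b, "alignment"))

    by_scaffold: dict[str, list[GenomicInterval]] = {}
    for iv in nodes:
        by_scaffold.setdefault(iv.scaffold, []).append(iv)
    for ivs in by_scaffold.values():
        ivs.sort(key=lambda v: (v.start, v.end))
        active: list[GenomicInterval] = []
        for iv in ivs:
            active = [a for a in active if a.end > iv.start]
            for a in active:
                edges.append((a, iv, "overlap"))
            active.append(iv)

    uf = _UnionFind()
    for iv in nodes:
        uf.find(iv)
    for a, b, _kind in edges:
        uf.union(a, b)

    members: dict[GenomicInterval, list] = {}
    comp_edges: dict[GenomicInterval, list] = {}
    for iv in nodes:
        members.setdefault(uf.find(iv), []).append(iv)
    for a, b, kind in edges:
        comp_edges.setdefault(uf.find(a), []).append((a, b, kind))

    return [
        DuplicationComponent(
            intervals=set(ivs),
            copy_number=len(set(ivs)),
            edges=comp_edges.get(root, []),
        )
        for root, ivs in members.items()
    ]


def filter_high_copy(
    pairs: list[DuplicationPair],
    components: list[DuplicationComponent],
    cfg: SDConfig | None = None,
) -> list[DuplicationPair]:
    """Remove pairs whose intervals sit in a component with copy number > max."""
    cfg = cfg or SDConfig()
    copy_of: dict[GenomicInterval, int] = {}
    for comp in components:
        for iv in comp.intervals:
            copy_of[iv] = comp.copy_number
    out = []
    for pair in pairs:
        if pair.interval_a not in copy_of or pair.interval_b not in copy_of:
            raise RuntimeError(
                f"pair {pair.interval_a}/{pair.interval_b} missing from the "
                "duplication graph; components must be built from these pairs"
            )
        if max(copy_of[pair.interval_a], copy_of[pair.interval_b]) <= cfg.max_copies:
            out.append(pair)
    return out


def summarize_sd(
    pairs: list[DuplicationPair],
    identity_bins: np.ndarray | None = None,
) -> SDSummary:
    """Pair count, non-redundant duplicated bases, and an identity histogram."""
    bins = identity_bins if identity_bins is not None else np.arange(0.5, 1.001, 0.01)
    intervals = [iv for p in pairs for iv in (p.interval_a, p.interval_b)]
    hist, edges_ = np.histogram([p.identity for p in pairs], bins=bins)
    return SDSummary(
        n_pairs=len(pairs),
        nonredundant_bases=total_bases(intervals),
        identity_bins=edges_,
        identity_histogram=hist,
    )


def divergence_to_age(identity: float, cfg: SDConfig | None = None) -> float:
    """Convert copy identity to an approximate duplication age in years.

    Uses a linear molecular clock: ``divergence_per_100ky`` of sequence
    divergence accumulates between copies every 100,000 years (default 0.5%,
    a configurable calibration, not a universal constant).
    """
    cfg = cfg or SDConfig()
    if not (0.0 <= identity <= 1.0):
        raise ValueError(f"identity {identity} outside [0, 1]")
    return (1.0 - identity) / cfg.divergence_per_100ky * 100_000.0
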