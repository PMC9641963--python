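"""Haplotype-vs-haplotype variant classification and heterozygosity spectrum.

Differences between the two haploid assemblies of one individual are read off
whole-genome alignment blocks and classified into SNVs, small (<= 50 bp) and
large (> 50 bp) indels, inversions, translocations (inverted or not), and
copy-number variants. Blocks are either consumed from a TSV derived from an
external whole-genome aligner, or computed at desk scale by the anchor-based
builder in this module (haplotypes are assumed to share scaffold names, so a
block is syntenic when its two scaffolds match).

A large indel is promoted to CNV when the gained/lost sequence closely
matches its flanking sequence — the signature of a tandem copy-number change
rather than novel sequence. SVs composed mostly of assembly gaps (N runs) are
dropped by :func:`gap_filter`.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import edlib
import numpy as np

from .regions import GenomicInterval, merge_intervals, overlap_bases
from .synthetic import SyntheticGenome, _revcomp

logger = logging.getLogger(__name__)

SMALL_INDEL_MAX = 50
VARIANT_CLASSES = (
    "SNV", "small_indel", "large_indel", "inversion",
    "translocation", "inverted_translocation", "CNV",
)


@dataclass(frozen=True)
class AlignmentBlock:
    a: GenomicInterval
    b: GenomicInterval
    orientation: str                      # "forward" | "reverse"
    ops: tuple[tuple[str, int], ...] | None = None
    # ops alphabet: M match, X mismatch, GA gap-in-A (extra base in B),
    # GB gap-in-B (extra base in A); None for blocks without base-level ops

    def __post_init__(self):
        if self.ops is None:
            return
        a_span = sum(n for op, n in self.ops if op in ("M", "X", "GB"))
        b_span = sum(n for op, n in self.ops if op in ("M", "X", "GA"))
        if a_span != self.a.length or b_span != self.b.length:
            raise ValueError("operation lengths inconsistent with block intervals")


@dataclass(frozen=True)
class VariantRecord:
    variant_class: str
    size: int
    a_scaffold: str
    a_pos: int
    b_scaffold: str
    b_pos: int
    indel_type: str | None = None         # "insertion" | "deletion" (B vs A)
    gap_fraction: float = 0.0

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.variant_class == "SNV" and self.size != 1:
            raise ValueError("SNV size must be 1")
        if self.variant_class == "small_indel" and self.size > SMALL_INDEL_MAX:
            raise ValueError("small indel larger than 50 bp")
        if self.variant_class == "large_indel" and self.size <= SMALL_INDEL_MAX:
            raise ValueError("large indel must exceed 50 bp")


@dataclass
class SpectrumSummary:
    counts: dict[str, int]
    histograms: dict[str, np.ndarray]
    bin_width: int
    peaks: list[int]
    snv_heterozygosity_percent: float | None = None
    full_spectrum_heterozygosity_percent: float | None = None


# -- block construction (desk-scale) ------------------------------------------


def _cigar_to_ops(cigar: str) -> list[tuple[str, int]]:
    translate = {"=": "M", "X": "X", "D": "GA", "I": "GB"}
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((translate[ch], int(num)))
            num = ""
    return ops


def _merge_ops(ops: list[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return tuple(merged)


def _nw_ops(seq_a: str, seq_b: str) -> list[tuple[str, int]]:
    if not seq_a and not seq_b:
        return []
    if not seq_a:
        return [("GA", len(seq_b))]
    if not seq_b:
        return [("GB", len(seq_a))]
    res = edlib.align(seq_a, seq_b, task="path", mode="NW")
    return _cigar_to_ops(res["cigar"])


def _refine_chain(
    chain: list[tuple[int, int]], seq_a: str, seq_b: str, k: int,
    sv_gap: int = 50,
) -> tuple[tuple[str, int], ...]:
    """Base-level operations for a forward anchor chain, piecewise by anchor.

    Inter-anchor segments of similar length are aligned by edit distance; a
    one-sided length jump above ``sv_gap`` is emitted as one explicit gap run
    (edit-distance alignment of mostly-random flanking sequence would
    otherwise smear a long indel into spurious mismatches and split gaps),
    with the remaining shared sequence aligned normally. The chain must
    already be sparsified (non-overlapping anchors, monotone on both genomes).
    """
    kept = chain
    ops: list[tuple[str, int]] = [("M", k)]
    for (pa, pb), (ca, cb) in zip(kept, kept[1:]):
        seg_a = seq_a[pa + k:ca]
        seg_b = seq_b[pb + k:cb]
        la, lb = len(seg_a), len(seg_b)
        if abs(la - lb) > sv_gap:
            if la > lb:  # extra sequence in A: deletion in B
                ops += _nw_ops(seg_a[:lb], seg_b)
                ops.append(("GB", la - lb))
            else:        # extra sequence in B: insertion
                ops += _nw_ops(seg_a, seg_b[:la])
                ops.append(("GA", lb - la))
        else:
            ops += _nw_ops(seg_a, seg_b)
        ops.append(("M", k))
    return _merge_ops(ops)


def align_haplotypes(
    genome_a: SyntheticGenome,
    genome_b: SyntheticGenome,
    k: int = 32,
    stride: int = 10,
    max_chain_gap: int = 30_000,
    break_gap: int = 250,
) -> list[AlignmentBlock]:
    """Anchor-and-chain block builder for two desk-scale haplotypes.

    Unique k-mer anchors are chained per scaffold pair and strand; a chain
    breaks where both haplotypes jump simultaneously (the signature of an
    inverted or relocated segment) but tolerates one-sided jumps (indels).
    Forward same-scaffold chains are finished with a base-level edit-distance
    alignment to produce per-column operations.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genome_b.sequences.items():
        for i in range(0, len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append((name, i))

    # anchors[(a_scaf, b_scaf, strand)] -> list of (a_pos, b_pos)
    anchors: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for a_name, seq in genome_a.sequences.items():
        for i in range(0, len(seq) - k + 1, stride):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            hits = index.get(kmer)
            if hits is not None:
                if len(hits) == 1:  # ambiguous anchors are left to the refinement
                    b_name, j = hits[0]
                    anchors.setdefault((a_name, b_name, "forward"), []).append((i, j))
                continue
            rc_hits = index.get(_revcomp(kmer))
            if rc_hits and len(rc_hits) == 1:
                b_name, j = rc_hits[0]
                anchors.setdefault((a_name, b_name, "reverse"), []).append((i, j))

    blocks: list[AlignmentBlock] = []
    for (a_name, b_name, strand), pts in anchors.items():
        pts.sort()
        chain: list[tuple[int, int]] = []
        sign = 1 if strand == "forward" else -1

        def flush():
            if len(chain) < 2:
                return
            # sparsify to non-overlapping anchors, monotone on both genomes
            kept = [chain[0]]
            for a, b in chain[1:]:
                if a - kept[-1][0] >= k and sign * (b - kept[-1][1]) >= k:
                    kept.append((a, b))
            if len(kept) < 2:
                return
            a0, a1 = kept[0][0], kept[-1][0] + k
            bs = [b for _, b in kept]
            b0, b1 = min(bs), max(bs) + k
            if a1 - a0 < k or b1 - b0 < k:
                return
            if strand == "forward":
                ops = _refine_chain(
                    kept, genome_a.sequences[a_name], genome_b.sequences[b_name], k
                )
                blocks.append(AlignmentBlock(
                    a=GenomicInterval(a_name, a0, a1),
                    b=GenomicInterval(b_name, b0, b1),
                    orientation="forward",
                    ops=ops,
                ))
            else:
                blocks.append(AlignmentBlock(
                    a=GenomicInterval(a_name, a0, a1),
                    b=GenomicInterval(b_name, b0, b1),
                    orientation="reverse",
                    ops=None,
                ))

        for a_pos, b_pos in pts:
            if chain:
                a_gap = a_pos - chain[-1][0]
                b_gap = sign * (b_pos - chain[-1][1])
                # a balanced simultaneous jump marks an inverted or relocated
                # segment; one-sided jumps are indels/CNVs handled in-block
                balanced = (
                    min(a_gap, b_gap) > break_gap
                    and abs(a_gap - b_gap) < 0.5 * min(a_gap, b_gap)
                )
                if (
                    b_gap < -k  # non-monotone partner
                    or a_gap > max_chain_gap
                    or b_gap > max_chain_gap
                    or balanced
                ):
                    flush()
                    chain = []
            chain.append((a_pos, b_pos))
        flush()

    blocks.sort(key=lambda blk: (blk.a.scaffold, blk.a.start, blk.b.scaffold, blk.b.start))
    return _drop_contained_blocks(blocks)


def _drop_contained_blocks(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Remove blocks whose A interval is contained in a larger block's."""
    kept: list[AlignmentBlock] = []
    for blk in sorted(blocks, key=lambda b: -b.a.length):
        contained = any(
            other.a.contains(blk.a) and other.b.scaffold == blk.b.scaffold
            and blk is not other
            for other in kept
        )
        if not contained:
            kept.append(blk)
    kept.sort(key=lambda blk: (blk.a.scaffold, blk.a.start, blk.b.scaffold, blk.b.start))
    return kept


def swap_haplotypes(block: AlignmentBlock) -> AlignmentBlock:
    """Exchange the roles of the two haplotypes in a block (A <-> B)."""
    swapped_ops = None
    if block.ops is not None:
        flip = {"M": "M", "X": "X", "GA": "GB", "GB": "GA"}
        swapped_ops = tuple((flip[op], n) for op, n in block.ops)
    return AlignmentBlock(a=block.b, b=block.a, orientation=block.orientation,
                          ops=swapped_ops)


# -- classification ------------------------------------------------------------


def _is_tandem_copy(inserted: str, flank_before: str, flank_after: str,
                    max_divergence: float = 0.2) -> bool:
    size = len(inserted)
    if size == 0:
        return False
    for flank in (flank_before, flank_after):
        if len(flank) < size // 2:
            continue
        res = edlib.align(inserted, flank, mode="NW")
        if res["editDistance"] >= 0 and res["editDistance"] / size <= max_divergence:
            return True
    return False


def classify_variants(
    blocks: list[AlignmentBlock],
    genome_a: SyntheticGenome | None = None,
    genome_b: SyntheticGenome | None = None,
    min_translocation_block: int = 1_000,
    same_scaffold_translocation_dist: int = 100_000,
) -> list[VariantRecord]:
    """Read variants off alignment blocks.

    SNVs come from mismatch columns and indels from maximal gap runs in
    forward syntenic blocks; reverse syntenic blocks are inversions;
    sufficiently large blocks joining different scaffolds (or distant
    positions of one scaffold) are translocations. When the genomes are
    supplied, a large indel whose sequence matches its flank is reclassified
    as a tandem CNV, and indels that merely re-describe a translocated
    segment are suppressed.
    """
    _check_block_consistency(blocks)
    variants: list[VariantRecord] = []
    translocation_a: list[GenomicInterval] = []
    translocation_b: list[GenomicInterval] = []

    def syntenic(blk: AlignmentBlock) -> bool:
        if blk.a.scaffold != blk.b.scaffold:
            return False
        return abs(blk.a.start - blk.b.start) <= same_scaffold_translocation_dist

    for blk in blocks:
        if not syntenic(blk):
            if blk.a.length >= min_translocation_block:
                cls = ("inverted_translocation" if blk.orientation == "reverse"
                       else "translocation")
                variants.append(VariantRecord(
                    cls, blk.a.length, blk.a.scaffold, blk.a.start,
                    blk.b.scaffold, blk.b.start,
                ))
                translocation_a.append(blk.a)
                translocation_b.append(blk.b)
            continue
        if blk.orientation == "reverse":
            variants.append(VariantRecord(
                "inversion", blk.a.length, blk.a.scaffold, blk.a.start,
                blk.b.scaffold, blk.b.start,
            ))
            continue
        if blk.ops is None:
            continue
        variants.extend(_variants_from_ops(blk, genome_a, genome_b))

    if translocation_a:
        variants = _suppress_translocation_echoes(
            variants, translocation_a, translocation_b
        )
    return variants


def _check_block_consistency(blocks: list[AlignmentBlock]) -> None:
    one_to_one = [
        b for b in blocks
        if b.orientation == "forward" and b.ops is not None
        and b.a.scaffold == b.b.scaffold
    ]
    by_scaffold: dict[str, list[AlignmentBlock]] = {}
    for blk in one_to_one:
        by_scaffold.setdefault(blk.a.scaffold, []).append(blk)
    for name, blks in by_scaffold.items():
        blks.sort(key=lambda b: b.a.start)
        for prev, nxt in zip(blks, blks[1:]):
            if nxt.a.start < prev.a.end:
                raise ValueError(
                    f"overlapping one-to-one blocks on {name}: "
                    f"{prev.a.start}-{prev.a.end} and {nxt.a.start}-{nxt.a.end}"
                )


def _variants_from_ops(
    blk: AlignmentBlock,
    genome_a: SyntheticGenome | None,
    genome_b: SyntheticGenome | None,
    indel_merge_gap: int = 10,
) -> list[VariantRecord]:
    out = []
    indels: list[tuple[int, int, int, str]] = []  # (a_pos, b_pos, size, type)
    a_pos, b_pos = blk.a.start, blk.b.start
    for op, n in blk.ops:
        if op == "M":
            a_pos += n
            b_pos += n
        elif op == "X":
            for j in range(n):
                out.append(VariantRecord(
                    "SNV", 1, blk.a.scaffold, a_pos + j, blk.b.scaffold, b_pos + j
                ))
            a_pos += n
            b_pos += n
        elif op == "GA":  # extra bases in B: insertion
            indels.append((a_pos, b_pos, n, "insertion"))
            b_pos += n
        elif op == "GB":  # extra bases in A: deletion in B
            indels.append((a_pos, b_pos, n, "deletion"))
            a_pos += n

    # a parsimony alignment can split one indel around accidental matches;
    # nearby same-type gap runs are one event, so merge their sizes
    merged: list[tuple[int, int, int, str]] = []
    for a0, b0, size, kind in indels:
        if merged:
            pa, pb, psize, pkind = merged[-1]
            near = (
                kind == pkind
                and a0 - (pa + (psize if kind == "deletion" else 0)) <= indel_merge_gap
                and b0 - (pb + (psize if kind == "insertion" else 0)) <= indel_merge_gap
            )
            if near:
                merged[-1] = (pa, pb, psize + size, pkind)
                continue
        merged.append((a0, b0, size, kind))

    for a0, b0, size, kind in merged:
        out.append(_indel_record(blk, a0, b0, size, kind, genome_a, genome_b))
    return out


def _indel_record(
    blk: AlignmentBlock,
    a_pos: int,
    b_pos: int,
    size: int,
    indel_type: str,
    genome_a: SyntheticGenome | None,
    genome_b: SyntheticGenome | None,
) -> VariantRecord:
    cls = "small_indel" if size <= SMALL_INDEL_MAX else "large_indel"
    gap_fraction = 0.0
    if cls == "large_indel":
        if indel_type == "insertion" and genome_b is not None:
            seq = genome_b.sequences[blk.b.scaffold]
            inserted = seq[b_pos:b_pos + size]
            gap_fraction = inserted.count("N") / max(size, 1)
            if _is_tandem_copy(inserted, seq[max(0, b_pos - size):b_pos],
                               seq[b_pos + size:b_pos + 2 * size]):
                cls = "CNV"
        elif indel_type == "deletion" and genome_a is not None:
            seq = genome_a.sequences[blk.a.scaffold]
            removed = seq[a_pos:a_pos + size]
            gap_fraction = removed.count("N") / max(size, 1)
            if _is_tandem_copy(removed, seq[max(0, a_pos - size):a_pos],
                               seq[a_pos + size:a_pos + 2 * size]):
                cls = "CNV"
    return VariantRecord(
        cls, size, blk.a.scaffold, a_pos, blk.b.scaffold, b_pos,
        indel_type=indel_type, gap_fraction=gap_fraction,
    )


def _suppress_translocation_echoes(
    variants: list[VariantRecord],
    translocation_a: list[GenomicInterval],
    translocation_b: list[GenomicInterval],
) -> list[VariantRecord]:
    """Drop indels that re-describe a translocated segment at its two loci."""
    out = []
    for v in variants:
        if v.variant_class not in ("small_indel", "large_indel", "CNV"):
            out.append(v)
            continue
        echo = False
        if v.indel_type == "deletion":
            iv = GenomicInterval(v.a_scaffold, v.a_pos, v.a_pos + v.size)
            echo = any(
                t.overlaps(iv) and min(t.end, iv.end) - max(t.start, iv.start)
                >= 0.5 * v.size
                for t in translocation_a
            )
        elif v.indel_type == "insertion":
            iv = GenomicInterval(v.b_scaffold, v.b_pos, v.b_pos + v.size)
            echo = any(
                t.overlaps(iv) and min(t.end, iv.end) - max(t.start, iv.start)
                >= 0.5 * v.size
                for t in translocation_b
            )
        if not echo:
            out.append(v)
    return out


# -- gap filter ----------------------------------------------------------------


def n_track_from_genome(genome: SyntheticGenome) -> dict[str, list[tuple[int, int]]]:
    """Per-scaffold merged intervals of N runs."""
    track: dict[str, list[tuple[int, int]]] = {}
    for name, seq in genome.sequences.items():
        runs = []
        start = None
        for i, base in enumerate(seq):
            if base == "N" and start is None:
                start = i
            elif base != "N" and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(seq)))
        if runs:
            track[name] = merge_intervals(runs)
    return track


def gap_filter(
    variants: list[VariantRecord],
    n_track_a: dict[str, list[tuple[int, int]]] | None = None,
    n_track_b: dict[str, list[tuple[int, int]]] | None = None,
) -> list[VariantRecord]:
    """Drop SVs in which more than half the feature consists of assembly gaps.

    Exactly half is retained (the rule is strict); SNVs are never dropped.
    With no N track the stored per-variant gap fractions are used; when both
    are absent everything is retained with a warning.
    """
    if n_track_a is None and n_track_b is None:
        if any(v.gap_fraction == 0.0 for v in variants):
            logger.warning("no N track supplied; gap filter using stored fractions only")
    out = []
    for v in variants:
        if v.variant_class == "SNV":
            out.append(v)
            continue
        frac = v.gap_fraction
        if v.indel_type == "deletion" and n_track_a is not None:
            frac = overlap_bases(v.a_pos, v.a_pos + v.size,
                                 n_track_a.get(v.a_scaffold, [])) / v.size
        elif v.indel_type == "insertion" and n_track_b is not None:
            frac = overlap_bases(v.b_pos, v.b_pos + v.size,
                                 n_track_b.get(v.b_scaffold, [])) / v.size
        elif v.indel_type is None and n_track_a is not None:
            frac = overlap_bases(v.a_pos, v.a_pos + v.size,
                                 n_track_a.get(v.a_scaffold, [])) / v.size
        if frac > 0.5:
            continue
        out.append(replace(v, gap_fraction=frac))
    return out


# -- spectrum ------------------------------------------------------------------


def size_spectrum(
    variants: list[VariantRecord],
    bin_width: int = 100,
    classes: tuple[str, ...] | None = None,
    peak_factor: float = 3.0,
    peak_min_count: int = 5,
) -> SpectrumSummary:
    """Per-class size histograms plus detected modal sizes of the SV spectrum.

    Peaks are local maxima of the pooled non-SNV size histogram that exceed
    both ``peak_factor`` times the median bin count and an absolute floor;
    reported values are bin lower edges (e.g. 300 for the 300 bp peak).
    """
    classes = classes or VARIANT_CLASSES
    counts = Counter(v.variant_class for v in variants)
    sizes_by_class: dict[str, list[int]] = {c: [] for c in classes}
    pooled: list[int] = []
    for v in variants:
        if v.variant_class in sizes_by_class:
            sizes_by_class[v.variant_class].append(v.size)
        if v.variant_class != "SNV":
            pooled.append(v.size)

    max_size = max((v.size for v in variants), default=0)
    n_bins = max_size // bin_width + 1 if variants else 0
    histograms = {}
    for cls in classes:
        hist = np.zeros(n_bins, dtype=int)
        for size in sizes_by_class[cls]:
            hist[size // bin_width] += 1
        histograms[cls] = hist

    peaks: list[int] = []
    if pooled:
        hist = np.zeros(n_bins, dtype=int)
        for size in pooled:
            hist[size // bin_width] += 1
        floor = max(peak_factor * float(np.median(hist)), peak_min_count)
        for i in range(n_bins):
            left = hist[i - 1] if i > 0 else 0
            right = hist[i + 1] if i + 1 < n_bins else 0
            if hist[i] >= floor and hist[i] >= left and hist[i] >= right:
                peaks.append(i * bin_width)

    return SpectrumSummary(
        counts={c: counts.get(c, 0) for c in classes},
        histograms=histograms,
        bin_width=bin_width,
        peaks=peaks,
    )


def heterozygosity_rates(
    variants: list[VariantRecord], aligned_bases: int
) -> tuple[float, float]:
    """(SNV %, full-spectrum %) heterozygosity over the aligned genome.

    The SNV rate counts mismatch columns; the full-spectrum rate counts all
    affected bases — each indel or SV contributes its size — so a handful of
    large variants can dominate it.
    """
    if aligned_bases <= 0:
        raise ValueError("aligned_bases must be > 0")
    n_snv = sum(1 for v in variants if v.variant_class == "SNV")
    affected = n_snv + sum(
        v.size for v in variants if v.variant_class != "SNV"
    )
    return 100.0 * n_snv / aligned_bases, 100.0 * affected / aligned_bases


def aligned_bases_of(blocks: list[AlignmentBlock]) -> int:
    """Total A-side bases covered by forward base-level blocks."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    for blk in blocks:
        if blk.orientation == "forward" and blk.ops is not None:
            ivs.setdefault(blk.a.scaffold, []).append((blk.a.start, blk.a.end))
    return sum(e - s for merged in map(merge_intervals, ivs.values()) for s, e in merged)
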