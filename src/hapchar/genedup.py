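"""Duplicated-gene calling from spliced-transcript multi-mapping.

A gene is called duplicated when its representative isoform maps to two or
more genomic locations with at most 10% divergence over at least 90% of the
spliced query. Eligibility requires a multi-exon model with a gene body of at
least 1 kb; one isoform (the longest spliced sequence) represents each gene.
When passing placements of different genes overlap the same target location,
the first gene in input order keeps the placement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .regions import GenomicInterval
from .sd import _cigar_identity
from .synthetic import SyntheticGenome

logger = logging.getLogger(__name__)

MIN_GENE_BODY = 1_000
MIN_EXONS = 2


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    transcript_id: str
    scaffold: str
    exons: tuple[tuple[int, int], ...]
    spliced_sequence: str

    def __post_init__(self):
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
        if len(self.spliced_sequence) != sum(e - s for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: spliced length != exon total")

    @property
    def gene_body_length(self) -> int:
        return self.exons[-1][1] - self.exons[0][0]

    @property
    def spliced_length(self) -> int:
        return len(self.spliced_sequence)


@dataclass(frozen=True)
class GeneAlignment:
    gene_id: str
    transcript_id: str
    target: GenomicInterval
    identity: float
    query_coverage: float
    rank: int

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ValueError("identity and query_coverage must lie in [0, 1]")


@dataclass
class GeneDuplication:
    gene_id: str
    copies: int
    placements: list[GenomicInterval]
    mode: str = "unclassified"        # tandem | interspersed | unclassified
    status: str = "resolved"          # resolved | collapsed
    missing_copies: int = 0


def select_isoforms(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """One representative isoform per eligible gene.

    Excludes genes with fewer than two exons (no intron) or a gene body under
    1 kb; among surviving isoforms of a gene, the longest spliced sequence is
    retained (ties broken by transcript id).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tr in transcripts:
        by_gene.setdefault(tr.gene_id, []).append(tr)
    out = []
    for gene_id in by_gene:
        eligible = [
            tr for tr in by_gene[gene_id]
            if len(tr.exons) >= MIN_EXONS and tr.gene_body_length >= MIN_GENE_BODY
        ]
        if eligible:
            eligible.sort(key=lambda tr: (-tr.spliced_length, tr.transcript_id))
            out.append(eligible[0])
    return out


def _exon_sequences(tr: TranscriptModel) -> list[str]:
    seqs = []
    pos = 0
    for s, e in tr.exons:
        seqs.append(tr.spliced_sequence[pos:pos + (e - s)])
        pos += e - s
    return seqs


def _spliced_to_genomic_offsets(tr: TranscriptModel, k: int, step: int) -> list[tuple[int, int]]:
    """(spliced position, genomic offset from gene-body start) for sampled k-mers."""
    body_start = tr.exons[0][0]
    out = []
    spliced_pos = 0
    for s, e in tr.exons:
        for i in range(0, e - s - k + 1, step):
            out.append((spliced_pos + i, s - body_start + i))
        spliced_pos += e - s
    return out


def map_transcripts(
    genome: SyntheticGenome,
    transcripts: list[TranscriptModel],
    k: int = 20,
    cluster_tolerance: int = 100,
    min_cluster_hits: int = 2,
    max_exon_divergence: float = 0.35,
) -> list[GeneAlignment]:
    """Desk-scale spliced mapping of each isoform to all genomic placements.

    Every exact k-mer hit of the spliced sequence is projected back to an
    implied gene-body start using the exon layout of the source gene (gene
    copies preserve that layout up to small indels); implied starts are
    clustered into candidate loci, and each exon is aligned within its locus
    by infix edit-distance alignment, accumulating identity over aligned
    columns and query coverage. Placements are reported best-first per
    transcript; ``rank`` preserves transcript input order for downstream
    conflict resolution.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genome.sequences.items():
        for i in range(0, len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append((name, i))

    out: list[GeneAlignment] = []
    for rank, tr in enumerate(transcripts):
        spliced = tr.spliced_sequence
        body_len = tr.gene_body_length
        implied: dict[str, list[int]] = {}
        for spos, goff in _spliced_to_genomic_offsets(tr, k, max(1, k // 4)):
            for name, gpos in index.get(spliced[spos:spos + k], []):
                implied.setdefault(name, []).append(gpos - goff)

        loci: list[tuple[str, int]] = []  # (scaffold, body start)
        for name, starts in implied.items():
            starts.sort()
            cluster: list[int] = []
            for p in starts + [starts[-1] + 10 * cluster_tolerance]:
                if cluster and p - cluster[-1] > cluster_tolerance:
                    if len(cluster) >= min_cluster_hits:
                        loci.append((name, int(np.median(cluster))))
                    cluster = []
                cluster.append(p)

        placements = []
        for name, body_start in loci:
            pad = 200
            region_start = max(0, body_start - pad)
            region = genome.sequences[name][region_start:body_start + body_len + pad]
            total_cols = total_matches = aligned_q = 0
            starts, ends = [], []
            for exon_seq in _exon_sequences(tr):
                res = edlib.align(exon_seq, region, task="path", mode="HW")
                if res["editDistance"] < 0:
                    continue
                if res["editDistance"] / max(len(exon_seq), 1) > max_exon_divergence:
                    continue
                ident, cols = _cigar_identity(res["cigar"])
                total_cols += cols
                total_matches += ident * cols
                aligned_q += len(exon_seq)
                loc = res["locations"][0]
                starts.append(region_start + loc[0])
                ends.append(region_start + loc[1] + 1)
            if total_cols == 0:
                continue
            placements.append(GeneAlignment(
                gene_id=tr.gene_id,
                transcript_id=tr.transcript_id,
                target=GenomicInterval(name, min(starts), max(ends)),
                identity=total_matches / total_cols,
                query_coverage=min(1.0, aligned_q / tr.spliced_length),
                rank=rank,
            ))
        placements.sort(key=lambda a: -(a.identity * a.query_coverage))
        out.extend(placements)
    return out


def _overlap_fraction(x: GenomicInterval, y: GenomicInterval) -> float:
    """Overlap as a fraction of the smaller interval."""
    if not x.overlaps(y):
        return 0.0
    inter = min(x.end, y.end) - max(x.start, y.start)
    return inter / min(x.length, y.length)


def call_duplications(
    alignments: list[GeneAlignment],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> list[GeneDuplication]:
    """Genes whose isoform has >= 2 passing placements after conflict resolution."""
    passing = [
        a for a in alignments
        if a.identity >= min_identity and a.query_coverage >= min_coverage
    ]
    by_gene: dict[str, list[GeneAlignment]] = {}
    gene_rank: dict[str, int] = {}
    for a in passing:
        by_gene.setdefault(a.gene_id, []).append(a)
        gene_rank[a.gene_id] = min(gene_rank.get(a.gene_id, a.rank), a.rank)

    # same-location conflicts across genes: first-mapped gene keeps the spot
    claimed: list[tuple[str, GenomicInterval]] = []
    kept: dict[str, list[GenomicInterval]] = {}
    for gene_id in sorted(by_gene, key=lambda g: gene_rank[g]):
        placements: list[GenomicInterval] = []
        for a in by_gene[gene_id]:
            if any(_overlap_fraction(a.target, p) > 0.5 for p in placements):
                continue  # duplicate report of the same locus for this gene
            if any(a.target.overlaps(iv) for owner, iv in claimed if owner != gene_id):
                continue
            placements.append(a.target)
        claimed.extend((gene_id, p) for p in placements)
        kept[gene_id] = placements

    out = []
    for gene_id, placements in kept.items():
        if len(placements) >= 2:
            placements = sorted(placements, key=lambda p: (p.scaffold, p.start))
            out.append(GeneDuplication(
                gene_id=gene_id, copies=len(placements), placements=placements
            ))
    out.sort(key=lambda d: d.gene_id)
    return out


def classify_mode(dup: GeneDuplication, tandem_max_gap: int = 500_000) -> str:
    """Tandem when all copies sit on one scaffold within the configured gap."""
    if len(dup.placements) < 2:
        raise ValueError("classification needs at least two placements")
    scaffolds = {p.scaffold for p in dup.placements}
    if len(scaffolds) > 1:
        return "interspersed"
    ordered = sorted(dup.placements, key=lambda p: p.start)
    max_gap = max(
        nxt.start - prev.end for prev, nxt in zip(ordered, ordered[1:])
    )
    return "tandem" if max_gap <= tandem_max_gap else "interspersed"


def flag_collapsed_genes(
    entries: list[GeneDuplication],
    copy_segments: list,
    overlap_fraction: float = 0.5,
    collapse_threshold: int = 2,
) -> list[GeneDuplication]:
    """Mark genes whose bodies sit in decoded high-copy (collapsed) regions.

    A gene is collapsed when at least half of its (first-placement) body
    overlaps depth segments decoded above copy number 2; the implied number
    of missing copies is the decoded copy number minus the assembled copies.
    """
    high = [seg for seg in copy_segments if seg.copy_number > collapse_threshold]
    out = []
    for entry in entries:
        body = entry.placements[0]
        covered = sum(
            max(0, min(body.end, seg.interval.end) - max(body.start, seg.interval.start))
            for seg in high
            if seg.interval.scaffold == body.scaffold
        )
        if body.length > 0 and covered / body.length >= overlap_fraction:
            decoded = max(
                seg.copy_number for seg in high
                if seg.interval.scaffold == body.scaffold
                and seg.interval.start < body.end and body.start < seg.interval.end
            )
            out.append(replace_status(entry, "collapsed", max(0, decoded - entry.copies)))
        else:
            out.append(replace_status(entry, "resolved", 0))
    return out


def replace_status(entry: GeneDuplication, status: str, missing: int) -> GeneDuplication:
    return GeneDuplication(
        gene_id=entry.gene_id, copies=entry.copies,
        placements=list(entry.placements), mode=entry.mode,
        status=status, missing_copies=missing,
    )


def compare_copy_numbers(
    dups_by_assembly: dict[str, dict[str, int]],
    group_a: tuple[str, str],
    group_b: tuple[str, str],
) -> list[str]:
    """Genes with >= 2 copies in both group-A assemblies and exactly 1 in both
    group-B assemblies.

    ``dups_by_assembly`` maps assembly name -> {gene id -> copy count}; a copy
    count of 1 must be stated explicitly (absence means the gene is not
    annotated in that assembly and it is excluded and logged).
    """
    for name in (*group_a, *group_b):
        if name not in dups_by_assembly:
            raise KeyError(f"no duplication calls for assembly {name!r}")
    all_genes = sorted(set().union(*(dups_by_assembly[n].keys()
                                     for n in (*group_a, *group_b))))
    out = []
    for gene in all_genes:
        counts = {}
        missing = False
        for name in (*group_a, *group_b):
            if gene not in dups_by_assembly[name]:
                logger.warning("gene %s absent from assembly %s; excluded", gene, name)
                missing = True
                break
            counts[name] = dups_by_assembly[name][gene]
        if missing:
            continue
        if all(counts[n] >= 2 for n in group_a) and all(counts[n] == 1 for n in group_b):
            out.append(gene)
    return out
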