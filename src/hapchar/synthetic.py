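"""Synthetic genomes, annotations, depth tracks and trio tables with planted truth.

Every generator is a pure function of its parameters and an integer seed, and
returns a :class:`TruthSet` recording each planted event so downstream recovery
can be scored exactly. Base composition is uniform over A/C/G/T; duplication
identity is realized by substitutions only, so the recorded identity fraction
has the same semantics as a self-alignment table's matched-base fraction.

The trio simulator emits two per-site tables, one per mapping target
(maternal / paternal assembly). A de novo mutation appears under its dual
genotype configuration — homozygous-reference parents with a heterozygous
offspring on the mapping that lacks the mutant allele, homozygous-alternative
parents on the mapping that carries it — and both rows share an integer
evidence token standing in for read-name overlap between the two call sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .regions import GenomicInterval

BASES = np.array(list("ACGT"))
DEFAULT_TE_LIBRARY = (300, 500, 4500)  # common mobile-element lengths, bp


class PlacementError(RuntimeError):
    """No room left to place a planted event."""


@dataclass(frozen=True)
class PlantedTE:
    interval: GenomicInterval
    element_length: int
    sequence: str


@dataclass(frozen=True)
class PlantedDuplication:
    source: GenomicInterval
    target: GenomicInterval
    identity: float          # achieved matched-base fraction of the copy
    mode: str                # "tandem" | "interspersed"


@dataclass(frozen=True)
class PlantedCollapse:
    interval: GenomicInterval
    true_copies: int
    assembled_copies: int


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    scaffold: str
    exons: tuple[tuple[int, int], ...]   # sorted, non-overlapping
    expected_copies: int
    placements: tuple[GenomicInterval, ...]   # gene-body location of each copy

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.scaffold, self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class PlantedDNM:
    scaffold: str
    position: int            # 1-based
    origin: str              # "maternal" | "paternal"


@dataclass(frozen=True)
class PlantedVariant:
    variant_class: str       # SNV | insertion | deletion | inversion | translocation | CNV
    size: int
    scaffold: str
    position: int            # 0-based on the reference haplotype


@dataclass
class TruthSet:
    """Machine-readable record of every planted event."""

    transposable_elements: list[PlantedTE] = field(default_factory=list)
    duplications: list[PlantedDuplication] = field(default_factory=list)
    collapses: list[PlantedCollapse] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)
    dnms: list[PlantedDNM] = field(default_factory=list)
    haplotype_variants: list[PlantedVariant] = field(default_factory=list)
    ab_violation_sites: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    repeat_track: list[GenomicInterval] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for iv in self.repeat_track:
            if iv.scaffold not in self.sequences:
                raise ValueError(f"repeat interval on unknown scaffold {iv.scaffold}")
            if not (0 <= iv.start < iv.end <= len(self.sequences[iv.scaffold])):
                raise ValueError(f"repeat interval out of bounds: {iv}")
        for name, seq in self.sequences.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"scaffold {name} contains non-ACGTN characters")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_genome(
    seed: int,
    scaffolds: list[int],
    te_library: tuple[int, ...] = DEFAULT_TE_LIBRARY,
    te_density: float = 0.0,
) -> tuple[SyntheticGenome, TruthSet]:
    """Random genome with interspersed mobile-element copies of fixed lengths.

    ``te_density`` is expected TE insertions per Mb per scaffold; copies of a
    per-length consensus are written over the background sequence (no
    coordinate shifts) and recorded in both the repeat track and the truth set.
    """
    if any(length < 10_000 for length in scaffolds):
        raise ValueError("scaffold lengths must be >= 10 kb")
    if te_density < 0:
        raise ValueError("te_density must be >= 0")
    rng = np.random.default_rng(seed)
    consensus = {length: _random_seq(rng, length) for length in te_library}

    sequences: dict[str, str] = {}
    truth = TruthSet()
    repeat_track: list[GenomicInterval] = []
    for idx, length in enumerate(scaffolds, start=1):
        name = f"scaf{idx}"
        seq = np.array(list(_random_seq(rng, length)))
        n_te = rng.poisson(te_density * length / 1e6) if te_density > 0 else 0
        placed: list[tuple[int, int]] = []
        for _ in range(n_te):
            el_len = int(rng.choice(list(te_library)))
            if el_len >= length:
                continue
            for _attempt in range(200):
                start = int(rng.integers(0, length - el_len))
                if all(start >= e or start + el_len <= s for s, e in placed):
                    break
            else:
                continue
            placed.append((start, start + el_len))
            seq[start:start + el_len] = list(consensus[el_len])
            iv = GenomicInterval(name, start, start + el_len)
            repeat_track.append(iv)
            truth.transposable_elements.append(
                PlantedTE(interval=iv, element_length=el_len, sequence=consensus[el_len])
            )
        sequences[name] = "".join(seq)

    genome = SyntheticGenome(sequences=sequences, repeat_track=sorted(repeat_track), seed=seed)
    return genome, truth


def _shift_interval(iv: GenomicInterval, scaffold: str, pos: int, delta: int) -> GenomicInterval:
    if iv.scaffold != scaffold or iv.end <= pos:
        return iv
    if iv.start >= pos:
        return GenomicInterval(iv.scaffold, iv.start + delta, iv.end + delta)
    # insertion lands inside the interval: stretch it
    return GenomicInterval(iv.scaffold, iv.start, iv.end + delta)


def _insert_sequence(
    genome: SyntheticGenome, truth: TruthSet, scaffold: str, pos: int, insert: str
) -> None:
    """Insert ``insert`` at ``pos``, shifting every recorded coordinate after it."""
    seq = genome.sequences[scaffold]
    genome.sequences[scaffold] = seq[:pos] + insert + seq[pos:]
    delta = len(insert)
    genome.repeat_track = [
        _shift_interval(iv, scaffold, pos, delta) for iv in genome.repeat_track
    ]
    truth.transposable_elements = [
        replace(te, interval=_shift_interval(te.interval, scaffold, pos, delta))
        for te in truth.transposable_elements
    ]
    truth.duplications = [
        replace(
            d,
            source=_shift_interval(d.source, scaffold, pos, delta),
            target=_shift_interval(d.target, scaffold, pos, delta),
        )
        for d in truth.duplications
    ]
    truth.genes = [
        replace(
            g,
            exons=tuple(
                (s + delta, e + delta) if g.scaffold == scaffold and s >= pos else (s, e)
                for s, e in g.exons
            ),
            placements=tuple(
                _shift_interval(p, scaffold, pos, delta) for p in g.placements
            ),
        )
        for g in truth.genes
    ]


def plant_duplications(
    genome: SyntheticGenome,
    n_events: int,
    length_range: tuple[int, int] = (2_000, 10_000),
    identity_range: tuple[float, float] = (0.90, 1.0),
    tandem_fraction: float = 0.5,
    seed: int = 0,
    truth: TruthSet | None = None,
) -> tuple[SyntheticGenome, TruthSet]:
    """Copy segments and re-insert them tandemly or at distant positions.

    The copy receives enough random substitutions to land within 0.5
    percentage points of the sampled identity; the truth records the achieved
    identity. Insertions shift all previously recorded coordinates.
    """
    lo, hi = identity_range
    if not (0.5 < lo <= hi <= 1.0):
        raise ValueError("identity_range must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    genome = SyntheticGenome(dict(genome.sequences), list(genome.repeat_track), genome.seed)
    truth = truth if truth is not None else TruthSet()

    names = list(genome.sequences)
    # planted events stay disjoint from one another so the recorded truth
    # (copy locations, identities, genes-in-duplication counts) is exact
    protected: list[GenomicInterval] = [d.source for d in truth.duplications]
    protected += [d.target for d in truth.duplications]

    def clear(iv: GenomicInterval) -> bool:
        return not any(iv.overlaps(p) for p in protected)

    for event in range(n_events):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        candidates = [n for n in names if len(genome.sequences[n]) > 2 * length]
        if not candidates:
            raise PlacementError(
                f"duplication event {event}: no scaffold can host a {length} bp copy"
            )
        for _attempt in range(200):
            scaffold = candidates[int(rng.integers(len(candidates)))]
            seq = genome.sequences[scaffold]
            src_start = int(rng.integers(0, len(seq) - length))
            source = GenomicInterval(scaffold, src_start, src_start + length)
            if clear(source):
                break
        else:
            raise PlacementError(f"duplication event {event}: no clear source segment")
        identity = float(rng.uniform(lo, hi))
        n_sub = int(round((1.0 - identity) * length))
        copy = np.array(list(seq[source.start:source.end]))
        if n_sub > 0:
            pos = rng.choice(length, size=n_sub, replace=False)
            for p in pos:
                current = copy[p]
                copy[p] = rng.choice([b for b in "ACGT" if b != current])
        achieved = 1.0 - n_sub / length
        tandem = bool(rng.random() < tandem_fraction)
        if tandem:
            ins_at = source.end
            if not clear(GenomicInterval(scaffold, ins_at, ins_at + 1)):
                raise PlacementError(
                    f"duplication event {event}: tandem slot at {scaffold}:{ins_at} occupied"
                )
        else:
            # distant: outside the source segment and any earlier planted event
            for _attempt in range(100):
                ins_at = int(rng.integers(0, len(seq) + 1))
                distant = (
                    ins_at <= source.start - length or ins_at >= source.end + length
                )
                if distant and clear(GenomicInterval(scaffold, ins_at, ins_at + 1)):
                    break
            else:
                raise PlacementError(f"duplication event {event}: no distant slot found")
        _insert_sequence(genome, truth, scaffold, ins_at, "".join(copy))
        if ins_at <= src_start:
            source = GenomicInterval(scaffold, src_start + length, src_start + 2 * length)
        target = GenomicInterval(scaffold, ins_at, ins_at + length)
        protected = [
            _shift_interval(p, scaffold, ins_at, length) for p in protected
        ] + [source, target]
        truth.duplications.append(
            PlantedDuplication(
                source=source,
                target=target,
                identity=achieved,
                mode="tandem" if tandem else "interspersed",
            )
        )
    return genome, truth


def plant_genes(
    genome: SyntheticGenome,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (2, 6),
    gene_length_range: tuple[int, int] = (1_200, 8_000),
    dup_overlap_fraction: float = 0.0,
    seed: int = 0,
    truth: TruthSet | None = None,
    min_exon: int = 40,
    max_tries: int = 200,
) -> tuple[SyntheticGenome, TruthSet]:
    """Mark multi-exon gene models on the genome, optionally inside duplications.

    Genes do not alter the sequence; they are coordinate annotations whose
    spliced transcripts are extracted by :func:`transcripts_from_truth`. A
    ``dup_overlap_fraction`` of the genes is placed fully inside a planted
    duplication source so their expected copy number exceeds one; truth
    records the location of every expected copy.
    """
    if gene_length_range[0] < 200:
        raise ValueError("gene_length_range minimum must be >= 200 bp")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else TruthSet()
    n_in_dup = int(round(dup_overlap_fraction * n_genes))
    dups = [d for d in truth.duplications if d.source.length >= gene_length_range[0] + 20]
    if n_in_dup > 0 and not dups:
        raise PlacementError("no planted duplication large enough to host a gene")

    occupied: list[GenomicInterval] = [g.body for g in truth.genes]
    for d in truth.duplications:
        occupied.append(d.target)  # keep genes out of duplicate copies

    for gi in range(n_genes):
        inside_dup = gi < n_in_dup
        for _attempt in range(max_tries):
            if inside_dup:
                dup = dups[int(rng.integers(len(dups)))]
                max_len = min(gene_length_range[1], dup.source.length - 20)
                length = int(rng.integers(gene_length_range[0], max_len + 1))
                start = int(
                    rng.integers(dup.source.start + 10, dup.source.end - length - 9)
                )
                scaffold = dup.source.scaffold
            else:
                scaffold = list(genome.sequences)[
                    int(rng.integers(len(genome.sequences)))
                ]
                scaffold_len = len(genome.sequences[scaffold])
                length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
                if scaffold_len <= length + 2:
                    continue
                start = int(rng.integers(0, scaffold_len - length))
            body = GenomicInterval(scaffold, start, start + length)
            if not any(body.overlaps(o) for o in occupied):
                break
        else:
            raise PlacementError(f"gene {gi}: no non-overlapping slot after {max_tries} tries")

        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_exons = max(1, min(n_exons, length // (2 * min_exon)))
        exons = _partition_exons(rng, start, length, n_exons, min_exon)
        placements = [body]
        for d in truth.duplications:
            if d.source.contains(body):
                offset = d.target.start - d.source.start
                placements.append(
                    GenomicInterval(d.target.scaffold, body.start + offset, body.end + offset)
                )
        truth.genes.append(
            PlantedGene(
                gene_id=f"gene{len(truth.genes) + 1}",
                scaffold=scaffold,
                exons=tuple(exons),
                expected_copies=len(placements),
                placements=tuple(placements),
            )
        )
        occupied.append(body)
    return genome, truth


def _partition_exons(
    rng: np.random.Generator, start: int, length: int, n_exons: int, min_exon: int
) -> list[tuple[int, int]]:
    if n_exons == 1:
        return [(start, start + length)]
    # alternate exon/intron blocks spanning exactly [start, start+length)
    n_blocks = 2 * n_exons - 1
    weights = rng.dirichlet(np.ones(n_blocks))
    sizes = np.maximum((weights * length).astype(int), min_exon)
    sizes[-1] = length - int(sizes[:-1].sum())
    if sizes[-1] < min_exon:  # rebalance from the largest block
        deficit = min_exon - sizes[-1]
        sizes[int(np.argmax(sizes[:-1]))] -= deficit
        sizes[-1] = min_exon
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(size)))
        pos += int(size)
    exons[-1] = (exons[-1][0], start + length)
    return exons


def transcripts_from_truth(genome: SyntheticGenome, truth: TruthSet) -> list:
    """Build one TranscriptModel per planted gene from its exon coordinates."""
    from .genedup import TranscriptModel

    out = []
    for gene in truth.genes:
        seq = genome.sequences[gene.scaffold]
        spliced = "".join(seq[s:e] for s, e in gene.exons)
        out.append(
            TranscriptModel(
                gene_id=gene.gene_id,
                transcript_id=f"{gene.gene_id}.t1",
                scaffold=gene.scaffold,
                exons=tuple(gene.exons),
                spliced_sequence=spliced,
            )
        )
    return out


def simulate_depth(
    genome: SyntheticGenome,
    mean_depth: float,
    dispersion: float = 3.0,
    bin_width: int = 100,
    collapses: list[PlantedCollapse] | None = None,
    seed: int = 0,
    truth: TruthSet | None = None,
) -> dict:
    """Per-bin read-depth tracks with elevated coverage over collapsed regions.

    Counts are negative binomial with variance ``dispersion × mean`` (Poisson
    when dispersion is exactly 1). Inside a collapsed interval the mean scales
    by true copies / assembled copies, emulating reads from missing copies
    piling onto the single assembled one.
    """
    from .collapse import DepthTrack

    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if dispersion < 1:
        raise ValueError("dispersion must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rng = np.random.default_rng(seed)
    collapses = list(collapses or [])
    if truth is not None:
        truth.collapses.extend(collapses)

    tracks: dict[str, DepthTrack] = {}
    for name, seq in genome.sequences.items():
        n_bins = len(seq) // bin_width
        means = np.full(n_bins, mean_depth, dtype=float)
        for col in collapses:
            if col.interval.scaffold != name:
                continue
            b0 = col.interval.start // bin_width
            b1 = -(-col.interval.end // bin_width)
            means[b0:b1] = mean_depth * col.true_copies / col.assembled_copies
        if dispersion == 1.0:
            counts = rng.poisson(means).astype(float)
        else:
            var = dispersion * means
            r = means**2 / (var - means)
            p = means / var
            counts = rng.negative_binomial(r, p).astype(float)
        tracks[name] = DepthTrack(scaffold=name, bin_width=bin_width, counts=counts)
    return tracks


# -- trio simulation ----------------------------------------------------------

DEFAULT_DEPTH_MEANS = {"offspring": 56.0, "father": 78.0, "mother": 84.0}
PASSING_ANNOTATIONS = {
    "QD": 20.0, "FS": 1.0, "MQ": 60.0,
    "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "SOR": 1.0,
}


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    return rng.choice([b for b in "ACGT" if b != ref])


def simulate_trio(
    genome: SyntheticGenome,
    het_rate: float = 0.0,
    n_dnm_maternal: int = 0,
    n_dnm_paternal: int = 0,
    depth_means: dict[str, float] | None = None,
    annotation_noise: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Two per-site trio genotype tables (maternal / paternal mapping) plus truth.

    Every genome position becomes one row in each table (base-pair-resolution
    calling). ``annotation_noise`` keys:

    - ``ab_violation``: fraction of true heterozygous offspring sites whose
      allelic balance is pushed outside [0.3, 0.7] (recorded in truth for
      false-negative-rate recovery);
    - ``site_filter_violation``: fraction of sites given a failing QD;
    - ``gq_violation`` / ``dp_violation``: fraction of sites where one
      individual fails the genotype-quality / depth window filter;
    - ``spurious_candidates``: count of DNM-like sites that qualify on only
      one mapping (no shared evidence token), exercising the intersection.
    """
    depth_means = dict(depth_means or DEFAULT_DEPTH_MEANS)
    noise = dict(annotation_noise or {})
    rng = np.random.default_rng(seed)
    individuals = ("offspring", "father", "mother")

    positions, chroms, refs = [], [], []
    for name, seq in genome.sequences.items():
        n = len(seq)
        chroms.extend([name] * n)
        positions.extend(range(1, n + 1))
        refs.extend(seq)
    n_sites = len(positions)

    n_dnm = n_dnm_maternal + n_dnm_paternal
    n_het = rng.binomial(n_sites, min(het_rate, 1.0)) if het_rate > 0 else 0
    if n_dnm + n_het > n_sites:
        raise ValueError("more planted events than available callable positions")
    special = rng.choice(n_sites, size=n_dnm + n_het, replace=False)
    dnm_idx = special[:n_dnm]
    het_idx = special[n_dnm:]

    def blank_table() -> pd.DataFrame:
        df = pd.DataFrame({"CHROM": chroms, "POS": positions, "REF": refs, "ALT": "."})
        for key, value in PASSING_ANNOTATIONS.items():
            df[key] = value
        for ind in individuals:
            mean = depth_means[ind]
            df[f"GT_{ind}"] = "0/0"
            df[f"DP_{ind}"] = rng.poisson(mean, size=n_sites)
            df[f"GQ_{ind}"] = 99
            df[f"AD_{ind}"] = 0
            df[f"EV_{ind}"] = -1
        return df

    tm = blank_table()  # maternal mapping
    tp = blank_table()  # paternal mapping

    truth = TruthSet()

    def set_het(df: pd.DataFrame, i: int, ind: str, ab: float | None = None) -> None:
        dp = int(df.at[i, f"DP_{ind}"])
        if ab is None:
            ad = int(rng.binomial(dp, 0.5))
            ad = min(max(ad, int(np.ceil(0.3 * dp))), int(0.7 * dp))
        else:
            ad = int(round(ab * dp))
        df.at[i, f"GT_{ind}"] = "0/1"
        df.at[i, f"AD_{ind}"] = ad

    def set_hom_alt(df: pd.DataFrame, i: int, ind: str) -> None:
        df.at[i, f"GT_{ind}"] = "1/1"
        df.at[i, f"AD_{ind}"] = int(df.at[i, f"DP_{ind}"])

    # inherited variation: parents drawn from allele frequency 0.5, child inherits
    ab_violation = float(noise.get("ab_violation", 0.0))
    for i in het_idx:
        i = int(i)
        alt = _alt_base(rng, refs[i])
        alleles = {
            parent: int(rng.integers(0, 2, size=2).sum())  # 0,1,2 alt alleles
            for parent in ("father", "mother")
        }
        # transmit one allele from each parent
        pat_allele = int(rng.random() < alleles["father"] / 2)
        mat_allele = int(rng.random() < alleles["mother"] / 2)
        child_g = pat_allele + mat_allele
        genos = {"father": alleles["father"], "mother": alleles["mother"],
                 "offspring": child_g}
        if all(g == 0 for g in genos.values()):
            continue
        violate = child_g == 1 and rng.random() < ab_violation
        for df in (tm, tp):
            df.at[i, "ALT"] = alt
            for ind, g in genos.items():
                if g == 1:
                    if ind == "offspring" and violate:
                        side = rng.random() < 0.5
                        set_het(df, i, ind, ab=0.15 if side else 0.85)
                    else:
                        set_het(df, i, ind)
                elif g == 2:
                    set_hom_alt(df, i, ind)
        if violate:
            truth.ab_violation_sites.append((chroms[i], positions[i]))

    # de novo mutations with the dual-mapping configuration and shared token
    for k, i in enumerate(dnm_idx):
        i = int(i)
        origin = "maternal" if k < n_dnm_maternal else "paternal"
        alt = _alt_base(rng, refs[i])
        token = 1000 + k
        # mapping that lacks the mutant allele: 0/0 parents, 0/1 child
        # mapping that carries it: 1/1 parents, 0/1 child
        absent, carries = (tp, tm) if origin == "maternal" else (tm, tp)
        for df, parent_gt in ((absent, "0/0"), (carries, "1/1")):
            df.at[i, "ALT"] = alt
            set_het(df, i, "offspring")
            df.at[i, f"EV_offspring"] = token
            for parent in ("father", "mother"):
                if parent_gt == "1/1":
                    set_hom_alt(df, i, parent)
        truth.dnms.append(PlantedDNM(chroms[i], positions[i], origin))

    # DNM-lookalikes on a single mapping only (no shared evidence token)
    n_spurious = int(noise.get("spurious_candidates", 0))
    if n_spurious:
        used = set(int(x) for x in special)
        free = [i for i in range(n_sites) if i not in used]
        pick = rng.choice(len(free), size=n_spurious, replace=False)
        for j, pi in enumerate(pick):
            i = free[int(pi)]
            df = tm if j % 2 == 0 else tp
            df.at[i, "ALT"] = _alt_base(rng, refs[i])
            set_het(df, i, "offspring")
            df.at[i, "EV_offspring"] = 5000 + j

    # generic filter violations
    frac = float(noise.get("site_filter_violation", 0.0))
    if frac > 0:
        for df in (tm, tp):
            hit = rng.random(n_sites) < frac
            df.loc[hit, "QD"] = 1.0
    frac = float(noise.get("gq_violation", 0.0))
    if frac > 0:
        for df in (tm, tp):
            hit = rng.random(n_sites) < frac
            df.loc[hit, "GQ_offspring"] = 30
    frac = float(noise.get("dp_violation", 0.0))
    if frac > 0:
        for df in (tm, tp):
            hit = rng.random(n_sites) < frac
            df.loc[hit, "DP_offspring"] = int(0.25 * depth_means["offspring"])

    return tm, tp, truth


# -- second haplotype ----------------------------------------------------------

SV_CLASSES = ("insertion", "deletion", "inversion", "translocation", "CNV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mutate_haplotype(
    genome: SyntheticGenome,
    snv_rate: float = 0.0,
    small_indel_rate: float = 0.0,
    sv_events: list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> tuple[SyntheticGenome, TruthSet]:
    """Derive a second haplotype by planting SNVs, small indels and SVs.

    ``sv_events`` is a list of (class, size) with class in
    insertion / deletion / inversion / translocation / CNV. A CNV is planted
    as a tandem extra copy; a translocation moves a segment to a different
    scaffold (or a distant position when the genome has one scaffold).
    Truth positions are coordinates on the input (reference) haplotype.
    """
    rng = np.random.default_rng(seed)
    sv_events = list(sv_events or [])
    if snv_rate < 0 or small_indel_rate < 0:
        raise ValueError("rates must be >= 0")
    for cls, _ in sv_events:
        if cls not in SV_CLASSES:
            raise ValueError(f"unknown SV class {cls!r}")

    truth = TruthSet()
    sequences = {name: seq for name, seq in genome.sequences.items()}
    names = list(sequences)

    # collect per-scaffold edits as (pos, kind, payload), applied right-to-left
    edits: dict[str, list[tuple[int, str, object]]] = {n: [] for n in names}
    reserved: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def reserve(name: str, start: int, end: int) -> bool:
        for s, e in reserved[name]:
            if start < e and s < end:
                return False
        reserved[name].append((start, end))
        return True

    for cls, size in sv_events:
        hosts = [n for n in names if len(sequences[n]) > 3 * size + 100]
        if not hosts:
            raise ValueError(f"SV {cls} of {size} bp larger than every scaffold")
        for _attempt in range(200):
            name = hosts[int(rng.integers(len(hosts)))]
            start = int(rng.integers(50, len(sequences[name]) - size - 50))
            if reserve(name, start - 1, start + size + 1):
                break
        else:
            raise PlacementError(f"no room for SV {cls} of {size} bp")
        segment = sequences[name][start:start + size]
        if cls == "insertion":
            edits[name].append((start, "ins", _random_seq(rng, size)))
        elif cls == "deletion":
            edits[name].append((start, "del", size))
        elif cls == "inversion":
            edits[name].append((start, "inv", size))
        elif cls == "CNV":
            edits[name].append((start + size, "ins", segment))
        elif cls == "translocation":
            other = [n for n in names if n != name]
            dest = other[int(rng.integers(len(other)))] if other else name
            for _attempt in range(200):
                dpos = int(rng.integers(50, len(sequences[dest]) - 50))
                far_enough = dest != name or abs(dpos - start) > 5 * size
                if far_enough and reserve(dest, dpos - 1, dpos + 1):
                    break
            else:
                raise PlacementError("no destination for translocation")
            edits[name].append((start, "del", size))
            edits[dest].append((dpos, "ins", segment))
        truth.haplotype_variants.append(PlantedVariant(cls, size, name, start))

    for name in names:
        length = len(sequences[name])
        n_snv = rng.binomial(length, min(snv_rate, 1.0)) if snv_rate > 0 else 0
        n_ind = rng.binomial(length, min(small_indel_rate, 1.0)) if small_indel_rate > 0 else 0
        if n_snv + n_ind == 0:
            continue
        pos = rng.choice(length, size=n_snv + n_ind, replace=False)
        for p in pos[:n_snv]:
            p = int(p)
            if not reserve(name, p, p + 1):
                continue
            ref = sequences[name][p]
            if ref == "N":
                continue
            edits[name].append((p, "sub", _alt_base(rng, ref)))
            truth.haplotype_variants.append(PlantedVariant("SNV", 1, name, p))
        for p in pos[n_snv:]:
            p = int(p)
            size = int(rng.integers(1, 11))
            if not reserve(name, p, p + size):
                continue
            if rng.random() < 0.5:
                edits[name].append((p, "ins", _random_seq(rng, size)))
                truth.haplotype_variants.append(PlantedVariant("insertion", size, name, p))
            else:
                if p + size >= len(sequences[name]):
                    continue
                edits[name].append((p, "del", size))
                truth.haplotype_variants.append(PlantedVariant("deletion", size, name, p))

    for name in names:
        seq = sequences[name]
        for pos, kind, payload in sorted(edits[name], key=lambda t: -t[0]):
            if kind == "sub":
                seq = seq[:pos] + str(payload) + seq[pos + 1:]
            elif kind == "ins":
                seq = seq[:pos] + str(payload) + seq[pos:]
            elif kind == "del":
                seq = seq[:pos] + seq[pos + int(payload):]
            elif kind == "inv":
                size = int(payload)
                seq = seq[:pos] + _revcomp(seq[pos:pos + size]) + seq[pos + size:]
        sequences[name] = seq

    hap = SyntheticGenome(sequences=sequences, repeat_track=list(genome.repeat_track),
                          seed=seed)
    return hap, truth
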