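"""Segmental-duplication filtering, graph copy numbers, and summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapchar import synthetic as syn
from hapchar.regions import GenomicInterval, total_bases
from hapchar.sd import (
    DuplicationPair,
    SDConfig,
    build_duplication_graph,
    divergence_to_age,
    filter_high_copy,
    filter_repeat_masked,
    naive_self_align,
    summarize_sd,
)


def _pair(a, b, identity=0.99):
    ia = GenomicInterval(*a)
    ib = GenomicInterval(*b)
    return DuplicationPair(interval_a=ia, interval_b=ib, identity=identity,
                           length=ia.length)


def _brute_force_components(pairs):
    """Transitive closure over alignment + overlap edges (independent oracle)."""
    nodes = sorted({iv for p in pairs for iv in (p.interval_a, p.interval_b)})
    idx = {iv: i for i, iv in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(adj, True)
    for p in pairs:
        adj[idx[p.interval_a], idx[p.interval_b]] = True
        adj[idx[p.interval_b], idx[p.interval_a]] = True
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if a.overlaps(b):
                adj[i, j] = adj[j, i] = True
    for _ in range(n):  # Floyd-Warshall style closure
        new = adj @ adj
        if (new.astype(bool) == adj).all():
            break
        adj = new.astype(bool)
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        members = frozenset(j for j in range(n) if adj[i, j])
        seen |= members
        comps.append(frozenset(nodes[j] for j in members))
    return set(comps)


class TestNaiveSelfAlign:
    def test_plain_genome_has_no_duplications(self):
        genome, _ = syn.generate_genome(seed=3, scaffolds=[50_000])
        assert naive_self_align(genome, min_length=1_000, min_identity=0.9) == []

    def test_exact_tandem_copy_found_once(self):
        genome, _ = syn.generate_genome(seed=4, scaffolds=[60_000])
        genome, truth = syn.plant_duplications(
            genome, n_events=1, length_range=(5_000, 5_000),
            identity_range=(1.0, 1.0), tandem_fraction=1.0, seed=5,
        )
        pairs = naive_self_align(genome, min_length=1_000, min_identity=0.9)
        assert len(pairs) == 1
        assert pairs[0].identity >= 0.999

    def test_recall_and_identity_against_alignment_oracle(self):
        """>=9/10 planted pairs recovered; identities near a full DP alignment."""
        from Bio import Align

        genome, _ = syn.generate_genome(seed=6, scaffolds=[600_000])
        genome, truth = syn.plant_duplications(
            genome, n_events=10, length_range=(3_000, 6_000),
            identity_range=(0.95, 0.95), tandem_fraction=0.5, seed=7,
        )
        pairs = naive_self_align(genome, min_length=1_000, min_identity=0.90)
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-1,
        )
        recovered = 0
        for dup in truth.duplications:
            hit = next(
                (
                    p for p in pairs
                    if (_jacc(p.interval_a, dup.source) > 0.8
                        and _jacc(p.interval_b, dup.target) > 0.8)
                    or (_jacc(p.interval_a, dup.target) > 0.8
                        and _jacc(p.interval_b, dup.source) > 0.8)
                ),
                None,
            )
            if hit is None:
                continue
            recovered += 1
            seq = genome.sequences[hit.interval_a.scaffold]
            sa = seq[hit.interval_a.start:hit.interval_a.end]
            sb = genome.sequences[hit.interval_b.scaffold][
                hit.interval_b.start:hit.interval_b.end
            ]
            aln = aligner.align(sa, sb)[0]
            matches = sum(
                x == y for x, y in zip(str(aln[0]), str(aln[1]))
                if x != "-" and y != "-"
            )
            assert abs(hit.identity - matches / aln.length) < 0.02
        assert recovered >= 9

    def test_oversized_genome_refused(self):
        genome = syn.SyntheticGenome(sequences={"s": "A" * 10_000_001})
        with pytest.raises(ValueError, match="external"):
            naive_self_align(genome)


def _jacc(x, y):
    if x.scaffold != y.scaffold or not x.overlaps(y):
        return 0.0
    inter = min(x.end, y.end) - max(x.start, y.start)
    return inter / (max(x.end, y.end) - min(x.start, y.start))


class TestFilterRepeatMasked:
    def test_over_threshold_pair_removed(self):
        pair = _pair(("s", 0, 1000), ("s", 5000, 6000))
        track = [GenomicInterval("s", 0, 950)]  # 95% of copy A masked
        assert filter_repeat_masked([pair], track) == []

    def test_empty_input_allowed(self):
        assert filter_repeat_masked([], [GenomicInterval("s", 0, 10)]) == []

    def test_matches_interval_intersection_oracle(self):
        rng = np.random.default_rng(0)
        pairs, track = [], []
        for i in range(20):
            a0 = int(rng.integers(0, 90_000))
            b0 = int(rng.integers(0, 90_000))
            pairs.append(_pair(("s", a0, a0 + 2_000), ("s", b0, b0 + 2_000)))
        for i in range(5):  # fully mask five pair-A intervals
            track.append(GenomicInterval("s", pairs[i].interval_a.start,
                                         pairs[i].interval_a.end))
        kept = filter_repeat_masked(pairs, track)

        def masked_frac(iv):
            return sum(
                max(0, min(iv.end, t.end) - max(iv.start, t.start))
                for t in track if t.scaffold == iv.scaffold
            ) / iv.length

        expected = [
            p for p in pairs
            if masked_frac(p.interval_a) <= 0.9 and masked_frac(p.interval_b) <= 0.9
        ]
        assert [(p.interval_a, p.interval_b) for p in kept] == [
            (p.interval_a, p.interval_b) for p in expected
        ]

    def test_exactly_at_threshold_retained(self):
        pair = _pair(("s", 0, 1000), ("s", 5000, 6000))
        track = [GenomicInterval("s", 0, 900)]  # exactly 90%
        assert len(filter_repeat_masked([pair], track)) == 1


class TestDuplicationGraph:
    def test_single_pair_two_copies(self):
        comps = build_duplication_graph([_pair(("s", 0, 100), ("s", 500, 600))])
        assert len(comps) == 1 and comps[0].copy_number == 2

    def test_transitive_chain_three_copies(self):
        comps = build_duplication_graph([
            _pair(("s", 0, 100), ("s", 500, 600)),
            _pair(("s", 500, 600), ("s", 900, 1000)),
        ])
        assert len(comps) == 1 and comps[0].copy_number == 3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 40), st.integers(0, 40)).filter(lambda t: t[0] != t[1]),
        min_size=1, max_size=50,
    ))
    def test_components_match_transitive_closure_oracle(self, edges):
        starts = [i * 7 for i in range(41)]  # overlapping ladder of intervals
        pairs = [
            _pair(("s", starts[i], starts[i] + 10), ("s", starts[j], starts[j] + 10))
            for i, j in edges
        ]
        comps = build_duplication_graph(pairs)
        got = {frozenset(c.intervals) for c in comps}
        assert got == _brute_force_components(pairs)
        for c in comps:
            assert c.copy_number == len(c.intervals)


class TestFilterHighCopy:
    @pytest.mark.parametrize("k,kept", [(19, True), (20, True), (21, False)])
    def test_copy_number_boundary(self, k, kept):
        # star of k disjoint copies: interval 0 aligned to each of 1..k-1
        pairs = [
            _pair(("s", 0, 100), ("s", 1000 * i, 1000 * i + 100))
            for i in range(1, k)
        ]
        comps = build_duplication_graph(pairs)
        out = filter_high_copy(pairs, comps)
        assert (len(out) == len(pairs)) is kept

    def test_pair_outside_graph_is_error(self):
        pairs = [_pair(("s", 0, 100), ("s", 500, 600))]
        comps = build_duplication_graph(pairs)
        rogue = _pair(("s", 9000, 9100), ("s", 9500, 9600))
        with pytest.raises(RuntimeError):
            filter_high_copy([rogue], comps)


class TestSummarizeAndAge:
    def test_empty_summary_is_zero(self):
        s = summarize_sd([])
        assert s.n_pairs == 0 and s.nonredundant_bases == 0
        assert s.identity_histogram.sum() == 0

    def test_shared_interval_bases_subadditive(self):
        p1 = _pair(("s", 0, 1000), ("s", 5000, 6000))
        p2 = _pair(("s", 0, 1000), ("s", 8000, 9000))
        s = summarize_sd([p1, p2])
        assert s.nonredundant_bases == 3000 < 4000

    def test_merged_bases_match_truth_footprint(self, dup_genome):
        genome, truth = dup_genome
        pairs = [
            DuplicationPair(d.source, d.target, d.identity,
                            length=d.source.length)
            for d in truth.duplications
        ]
        s = summarize_sd(pairs)
        footprint = total_bases(
            [d.source for d in truth.duplications]
            + [d.target for d in truth.duplications]
        )
        assert s.nonredundant_bases == footprint

    def test_merged_bases_invariant_under_reordering(self, dup_genome):
        _, truth = dup_genome
        pairs = [
            DuplicationPair(d.source, d.target, d.identity, length=d.source.length)
            for d in truth.duplications
        ]
        assert (summarize_sd(pairs).nonredundant_bases
                == summarize_sd(pairs[::-1]).nonredundant_bases)

    @pytest.mark.parametrize("identity,age", [(1.0, 0.0), (0.995, 100_000.0),
                                              (0.99, 200_000.0)])
    def test_divergence_to_age_linear_clock(self, identity, age):
        assert divergence_to_age(identity) == pytest.approx(age)

    def test_age_rejects_invalid_identity(self):
        with pytest.raises(ValueError):
            divergence_to_age(1.2)


class TestFilterMonotonicity:
    def test_tightening_thresholds_never_grows_retained_set(self, dup_genome):
        genome, truth = dup_genome
        pairs = naive_self_align(genome, min_length=1_000, min_identity=0.9)
        track = genome.repeat_track
        prev = None
        for thr in (0.95, 0.90, 0.50, 0.10):
            kept = {(p.interval_a, p.interval_b)
                    for p in filter_repeat_masked(pairs, track, SDConfig(masked_threshold=thr))}
            if prev is not None:
                assert kept <= prev
            prev = kept
        comps = build_duplication_graph(pairs)
        prev = None
        for mc in (30, 20, 10, 2):
            kept = {(p.interval_a, p.interval_b)
                    for p in filter_high_copy(pairs, comps, SDConfig(max_copies=mc))}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_recall_of_planted_duplications(self, dup_genome):
        """Planted, unmasked, full-length duplications recovered at >=95%."""
        genome, truth = dup_genome
        pairs = naive_self_align(genome, min_length=1_000, min_identity=0.90)
        eligible = [d for d in truth.duplications if d.identity >= 0.92]
        found = sum(
            1 for d in eligible
            if any(
                (_jacc(p.interval_a, d.source) > 0.8 and _jacc(p.interval_b, d.target) > 0.8)
                or (_jacc(p.interval_a, d.target) > 0.8 and _jacc(p.interval_b, d.source) > 0.8)
                for p in pairs
            )
        )
        assert found / len(eligible) >= 0.95
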