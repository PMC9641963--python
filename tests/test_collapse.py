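"""Copy-number HMM: baseline, emissions, Viterbi vs brute force, summaries."""
import itertools

import numpy as np
import pytest

from hapchar import synthetic as syn
from hapchar.collapse import (
    CopyNumberHMM,
    DepthTrack,
    NBEmissionModel,
    busco_depth_check,
    estimate_baseline,
    missing_bases,
    nb_params,
    path_log_likelihood,
    summary_percent,
    viterbi_decode,
)
from hapchar.regions import GenomicInterval
from hapchar.synthetic import PlantedCollapse


def _brute_force_path(track, hmm):
    """Exhaustive enumeration of all state paths (oracle for tiny instances)."""
    log_e = hmm.emission.log_emission_matrix(track.counts)
    log_t = hmm.log_transition_matrix()
    n_states, n_bins = log_e.shape
    paths = np.array(list(itertools.product(range(n_states), repeat=n_bins)))
    ll = np.log(1.0 / n_states) + log_e[paths[:, 0], 0]
    for t in range(1, n_bins):
        ll += log_t[paths[:, t - 1], paths[:, t]] + log_e[paths[:, t], t]
    best = int(np.argmax(ll))
    return paths[best], float(ll[best])


class TestBaseline:
    def test_recovers_mean_from_overdispersed_track(self):
        genome, _ = syn.generate_genome(seed=10, scaffolds=[1_000_000])
        track = syn.simulate_depth(genome, mean_depth=60, dispersion=3, seed=1)["scaf1"]
        mu2, var2 = estimate_baseline(track)
        assert abs(mu2 - 60) <= 2
        assert var2 > mu2  # overdispersed

    def test_constant_track_gives_exact_mean_zero_variance(self):
        mu2, var2 = estimate_baseline(DepthTrack("s", 100, np.full(2000, 60.0)))
        assert mu2 == 60.0 and var2 == 0.0

    def test_mode_robust_to_copy4_contamination(self):
        genome, _ = syn.generate_genome(seed=11, scaffolds=[1_000_000])
        col = PlantedCollapse(GenomicInterval("scaf1", 0, 100_000), 4, 2)
        track = syn.simulate_depth(genome, mean_depth=60, dispersion=3,
                                   collapses=[col], seed=2)["scaf1"]
        mu2, _ = estimate_baseline(track)
        assert abs(mu2 - 60) <= 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(DepthTrack("s", 100, np.full(500, 60.0)))


class TestNBParams:
    def test_copy_two_is_identity(self):
        assert nb_params(2, 60.0, 180.0) == (60.0, 180.0)

    def test_linear_scaling(self):
        mu4, var4 = nb_params(4, 60.0, 180.0)
        assert mu4 == 120.0 and var4 == 360.0

    def test_copy_zero_uses_epsilon_floor(self):
        mu0, var0 = nb_params(0, 60.0, 180.0, epsilon0=0.02)
        assert mu0 == pytest.approx(1.2)
        assert var0 == pytest.approx(1.2 * 1.01)

    def test_variance_floored_above_mean(self):
        _, var = nb_params(1, 60.0, 60.5)  # nearly Poisson baseline
        mu, _ = nb_params(1, 60.0, 60.5)
        assert var > mu

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            nb_params(2, 0.0, 10.0)


class TestViterbi:
    def _hmm(self, max_state=5):
        return CopyNumberHMM(
            emission=NBEmissionModel(mu2=60.0, var2=180.0, max_state=max_state),
            min_segment_bins=1,
        )

    def test_constant_diploid_depth_decodes_state_two(self):
        track = DepthTrack("s", 100, np.full(50, 60.0))
        path, segs = viterbi_decode(track, self._hmm())
        assert (path == 2).all()
        assert len(segs) == 1 and segs[0].copy_number == 2

    def test_all_zero_track_decodes_state_zero(self):
        track = DepthTrack("s", 100, np.zeros(30))
        path, _ = viterbi_decode(track, self._hmm())
        assert (path == 0).all()

    def test_doubled_depth_segment_matches_brute_force(self):
        """State-4 plateau in the middle of a diploid track; 8-bin, 5-state oracle."""
        counts = np.array([58, 62, 60, 118, 122, 120, 61, 59], dtype=float)
        track = DepthTrack("s", 100, counts)
        hmm = CopyNumberHMM(
            emission=NBEmissionModel(mu2=60.0, var2=180.0, max_state=4),
            epsilon_transition=0.01,  # three bins of evidence must afford a switch
            min_segment_bins=1,
        )
        path, _ = viterbi_decode(track, hmm)
        oracle, oracle_ll = _brute_force_path(track, hmm)
        assert (path == oracle).all()
        assert (path[3:6] == 4).all()
        assert path_log_likelihood(path, track, hmm) == pytest.approx(oracle_ll)

    def test_doubled_depth_ten_of_thirty_bins_decodes_state_four(self):
        """Ten doubled-depth bins overcome the sticky default transitions."""
        rng = np.random.default_rng(7)
        counts = np.concatenate([
            rng.poisson(60, 10), rng.poisson(120, 10), rng.poisson(60, 10),
        ]).astype(float)
        track = DepthTrack("s", 100, counts)
        path, segs = viterbi_decode(track, self._hmm(max_state=4))
        assert (path[10:20] == 4).all()
        assert (path[:10] == 2).all() and (path[20:] == 2).all()
        assert [s.copy_number for s in segs] == [2, 4, 2]

    @pytest.mark.parametrize("seed,n_bins,max_state", [
        (0, 12, 2), (1, 12, 2), (2, 6, 4), (3, 6, 4),
    ])
    def test_viterbi_equals_enumeration_on_random_tracks(self, seed, n_bins, max_state):
        rng = np.random.default_rng(seed)
        means = rng.choice([30, 60, 120, 180][:max_state + 1], size=n_bins)
        track = DepthTrack("s", 100, rng.poisson(means).astype(float))
        hmm = self._hmm(max_state=max_state)
        path, _ = viterbi_decode(track, hmm)
        oracle, _ = _brute_force_path(track, hmm)
        assert (path == oracle).all()

    def test_decoded_path_beats_all_state_two(self):
        rng = np.random.default_rng(8)
        counts = np.concatenate([rng.poisson(60, 30), rng.poisson(180, 30)])
        track = DepthTrack("s", 100, counts.astype(float))
        hmm = self._hmm()
        path, _ = viterbi_decode(track, hmm)
        assert (path_log_likelihood(path, track, hmm)
                >= path_log_likelihood(np.full(60, 2), track, hmm))

    def test_scale_consistency(self):
        """Multiplying counts and the baseline by k leaves the path unchanged."""
        rng = np.random.default_rng(9)
        counts = np.concatenate([rng.poisson(60, 40), rng.poisson(120, 40)]).astype(float)
        t1 = DepthTrack("s", 100, counts)
        t2 = DepthTrack("s", 100, counts * 3)
        h1 = self._hmm()
        h2 = CopyNumberHMM(
            emission=NBEmissionModel(mu2=180.0, var2=540.0, max_state=5),
            min_segment_bins=1,
        )
        p1, _ = viterbi_decode(t1, h1)
        p2, _ = viterbi_decode(t2, h2)
        assert (p1 == p2).mean() > 0.95

    def test_per_bin_recovery_on_planted_copies(self):
        """>= 95% of bins decode to the true state on the standard scenario."""
        genome, _ = syn.generate_genome(seed=20, scaffolds=[500_000])
        collapses = [
            PlantedCollapse(GenomicInterval("scaf1", 50_000, 80_000), 1, 2),
            PlantedCollapse(GenomicInterval("scaf1", 150_000, 180_000), 3, 2),
            PlantedCollapse(GenomicInterval("scaf1", 250_000, 280_000), 4, 2),
            PlantedCollapse(GenomicInterval("scaf1", 350_000, 380_000), 6, 2),
        ]
        track = syn.simulate_depth(genome, mean_depth=60, dispersion=3,
                                   collapses=collapses, seed=21)["scaf1"]
        mu2, var2 = estimate_baseline(track)
        hmm = CopyNumberHMM(emission=NBEmissionModel(mu2=mu2, var2=var2))
        path, _ = viterbi_decode(track, hmm)
        truth = np.full(track.n_bins, 2)
        for c in collapses:
            truth[c.interval.start // 100:c.interval.end // 100] = c.true_copies
        assert (path == truth).mean() >= 0.95

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            viterbi_decode(DepthTrack("s", 100, np.array([])), self._hmm())


class TestMissingBases:
    def _seg(self, start, end, cn):
        from hapchar.collapse import CopyNumberSegment
        return CopyNumberSegment(GenomicInterval("s", start, end), cn,
                                 mean_depth=30.0 * cn, length_bins=(end - start) // 100)

    def test_no_collapse_gives_zero(self):
        assert missing_bases([self._seg(0, 10_000, 2)]) == 0

    def test_copy4_segment_arithmetic(self):
        assert missing_bases([self._seg(0, 10_000, 4)]) == 10_000

    def test_recovery_within_ten_percent_of_truth(self):
        genome, _ = syn.generate_genome(seed=30, scaffolds=[500_000])
        collapses = [
            PlantedCollapse(GenomicInterval("scaf1", 100_000, 150_000), 4, 2),
            PlantedCollapse(GenomicInterval("scaf1", 300_000, 340_000), 6, 2),
        ]
        track = syn.simulate_depth(genome, mean_depth=60, dispersion=3,
                                   collapses=collapses, seed=31)["scaf1"]
        mu2, var2 = estimate_baseline(track)
        hmm = CopyNumberHMM(emission=NBEmissionModel(mu2=mu2, var2=var2))
        _, segs = viterbi_decode(track, hmm)
        truth = sum(c.interval.length * (c.true_copies - 2) / 2 for c in collapses)
        assert abs(missing_bases(segs) - truth) / truth <= 0.10

    def test_invalid_assembled_copies(self):
        with pytest.raises(ValueError):
            missing_bases([], assembled_copies=0)


class TestBuscoDepthCheck:
    def test_printed_summary_fraction(self):
        assert summary_percent(285, 439) == 65.0

    def test_copy_at_exact_threshold_passes(self):
        tracks = {"s": DepthTrack("s", 100, np.full(100, 30.5))}
        genes = {"g": [GenomicInterval("s", 0, 2_000)]}
        status, pct = busco_depth_check(genes, tracks, mean_depth=61.0)
        assert status["g"] == "pass" and pct == 100.0

    def test_true_copies_pass_spurious_copy_fails(self):
        genome, _ = syn.generate_genome(seed=40, scaffolds=[100_000])
        tracks = syn.simulate_depth(genome, mean_depth=60, dispersion=3, seed=41,
                                    collapses=[PlantedCollapse(
                                        GenomicInterval("scaf1", 60_000, 70_000), 1, 4)])
        genes = {
            "true_dup": [GenomicInterval("scaf1", 10_000, 14_000),
                         GenomicInterval("scaf1", 30_000, 34_000)],
            "spurious": [GenomicInterval("scaf1", 62_000, 66_000)],
        }
        status, _ = busco_depth_check(genes, tracks, mean_depth=60)
        assert status["true_dup"] == "pass"
        assert status["spurious"] == "fail"  # quarter-depth copy

    def test_gene_without_bins_is_indeterminate(self):
        tracks = {"s": DepthTrack("s", 100, np.full(10, 60.0))}
        genes = {"g": [GenomicInterval("other", 0, 1_000)],
                 "ok": [GenomicInterval("s", 0, 500)]}
        status, pct = busco_depth_check(genes, tracks, mean_depth=60)
        assert status["g"] == "indeterminate"
        assert pct == 100.0  # indeterminate genes leave the denominator
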