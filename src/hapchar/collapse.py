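"""Copy-number decoding of binned read depth with a negative-binomial HMM.

Collapsed duplications — multiple near-identical copies assembled as one —
show up as proportionally elevated mapped read depth. Each copy number c in
0..max_state is a hidden state whose emission is negative binomial with mean
(c/2)·mu2 and variance (c/2)·var2, where (mu2, var2) describe depth at
copy-number-two (normal diploid) sites. The chain is sticky: the probability
of staying in a state is 1 − epsilon, with epsilon split uniformly among the
other states, matching 100 bp bins against multi-kilobase duplications.
Decoding is by Viterbi so each reported segment is part of one globally
consistent path.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regions import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class DepthTrack:
    scaffold: str
    bin_width: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("depth counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class NBEmissionModel:
    mu2: float
    var2: float
    max_state: int = 12
    epsilon0: float = 0.02   # copy-0 mean as a fraction of mu2

    def __post_init__(self):
        if self.mu2 <= 0:
            raise ValueError("mu2 must be > 0")
        self.poisson = self.var2 <= self.mu2  # under-dispersed: Poisson fallback

    def params(self, c: int) -> tuple[float, float]:
        """(mean, variance) of the depth distribution at copy number c."""
        if c < 0:
            raise ValueError("copy number must be >= 0")
        mu_c = self.epsilon0 * self.mu2 if c == 0 else (c / 2.0) * self.mu2
        var_c = max((c / 2.0) * self.var2, mu_c * 1.01)
        return mu_c, var_c

    def log_emission_matrix(self, counts: np.ndarray) -> np.ndarray:
        """(n_states, n_bins) log-probabilities of each bin under each state."""
        k = np.round(counts).astype(int)
        rows = []
        for c in range(self.max_state + 1):
            mu_c, var_c = self.params(c)
            if self.poisson:
                rows.append(stats.poisson.logpmf(k, mu_c))
            else:
                r = mu_c**2 / (var_c - mu_c)
                p = mu_c / var_c
                rows.append(stats.nbinom.logpmf(k, r, p))
        return np.vstack(rows)


def nb_params(c: int, mu2: float, var2: float, epsilon0: float = 0.02) -> tuple[float, float]:
    """Depth (mean, variance) at copy number ``c`` given the diploid baseline."""
    return NBEmissionModel(mu2=mu2, var2=var2, epsilon0=epsilon0).params(c)


@dataclass
class CopyNumberHMM:
    emission: NBEmissionModel
    epsilon_transition: float = 1e-4
    min_segment_bins: int = 5

    @property
    def n_states(self) -> int:
        return self.emission.max_state + 1

    def log_transition_matrix(self) -> np.ndarray:
        n = self.n_states
        if n < 3:
            raise ValueError("max_state must be >= 2")
        mat = np.full((n, n), self.epsilon_transition / (n - 1))
        np.fill_diagonal(mat, 1.0 - self.epsilon_transition)
        return np.log(mat)


@dataclass
class CopyNumberSegment:
    interval: GenomicInterval
    copy_number: int
    mean_depth: float
    length_bins: int


def estimate_baseline(
    track: DepthTrack | list[DepthTrack],
    trim: tuple[float, float] = (0.01, 0.99),
    min_bins: int = 1_000,
) -> tuple[float, float]:
    """Diploid-depth baseline (mu2, var2) from a depth track.

    The diploid peak is located as the mode of the trimmed, lightly smoothed
    integer depth histogram (robust to collapsed and zero-depth contamination,
    unlike a global mean; ties resolve to the lower depth), and mu2 is then
    the mean of the bins within [0.5, 1.5] times that mode, which removes the
    skew bias of the raw mode while still excluding other copy-number states.
    var2 is the variance of bins within mu2 ± 3·sqrt(mu2).
    """
    tracks = track if isinstance(track, list) else [track]
    counts = np.concatenate([t.counts for t in tracks])
    if len(counts) < min_bins:
        raise ValueError(f"need >= {min_bins} bins to estimate a depth baseline")
    lo, hi = np.quantile(counts, trim)
    trimmed = counts[(counts >= lo) & (counts <= hi)]
    hist = np.bincount(np.round(trimmed).astype(int)).astype(float)
    smoothed = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    mode = int(np.argmax(smoothed))  # argmax takes the lowest index on ties
    window = counts[(counts >= 0.5 * mode) & (counts <= 1.5 * mode)]
    mu2 = float(window.mean()) if len(window) else float(mode)
    halo = counts[np.abs(counts - mu2) <= 3.0 * np.sqrt(max(mu2, 1.0))]
    var2 = float(np.var(halo)) if len(halo) > 1 else 0.0
    return mu2, var2


def viterbi_decode(
    track: DepthTrack, hmm: CopyNumberHMM
) -> tuple[np.ndarray, list[CopyNumberSegment]]:
    """Most probable copy-number path and its merged segments.

    Runs log-space Viterbi, merges runs of equal states into segments, then
    absorbs segments shorter than ``min_segment_bins`` into whichever
    neighboring state explains their bins better.
    """
    if track.n_bins == 0:
        raise ValueError("empty depth track")
    log_e = hmm.emission.log_emission_matrix(track.counts)
    if not np.all(np.isfinite(np.max(log_e, axis=0))):
        bad = int(np.nonzero(~np.isfinite(np.max(log_e, axis=0)))[0][0])
        raise FloatingPointError(f"non-finite emission log-likelihood at bin {bad}")
    log_t = hmm.log_transition_matrix()
    n_states, n_bins = log_e.shape

    delta = np.log(np.full(n_states, 1.0 / n_states)) + log_e[:, 0]
    back = np.zeros((n_bins, n_states), dtype=int)
    for t in range(1, n_bins):
        scores = delta[:, None] + log_t          # prev state x next state
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(n_states)] + log_e[:, t]

    path = np.zeros(n_bins, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n_bins - 1, 0, -1):
        path[t - 1] = back[t, path[t]]

    path = _absorb_short_segments(path, log_e, hmm.min_segment_bins)
    return path, _segments_from_path(path, track)


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, state) runs of equal state."""
    runs = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            runs.append((start, i, int(path[start])))
            start = i
    return runs


def _absorb_short_segments(
    path: np.ndarray, log_e: np.ndarray, min_bins: int
) -> np.ndarray:
    path = path.copy()
    for _ in range(len(path)):
        runs = _runs(path)
        if len(runs) <= 1:
            break
        short = [
            (end - start, idx) for idx, (start, end, _s) in enumerate(runs)
            if end - start < min_bins
        ]
        if not short:
            break
        _, idx = min(short)
        start, end, _state = runs[idx]
        options = []
        if idx > 0:
            options.append(runs[idx - 1][2])
        if idx + 1 < len(runs):
            options.append(runs[idx + 1][2])
        best = max(options, key=lambda s: log_e[s, start:end].sum())
        path[start:end] = best
    return path


def _segments_from_path(path: np.ndarray, track: DepthTrack) -> list[CopyNumberSegment]:
    w = track.bin_width
    return [
        CopyNumberSegment(
            interval=GenomicInterval(track.scaffold, start * w, end * w),
            copy_number=state,
            mean_depth=float(track.counts[start:end].mean()),
            length_bins=end - start,
        )
        for start, end, state in _runs(path)
    ]


def path_log_likelihood(
    path: np.ndarray, track: DepthTrack, hmm: CopyNumberHMM
) -> float:
    """Joint log-likelihood of a given state path for the observed bins."""
    log_e = hmm.emission.log_emission_matrix(track.counts)
    log_t = hmm.log_transition_matrix()
    total = np.log(1.0 / hmm.n_states) + log_e[path[0], 0]
    for t in range(1, len(path)):
        total += log_t[path[t - 1], path[t]] + log_e[path[t], t]
    return float(total)


def missing_bases(
    segments: list[CopyNumberSegment], assembled_copies: int = 2
) -> float:
    """Bases absent from the assembly implied by collapsed segments.

    For each segment decoded above the assembled copy number, the assembled
    sequence represents ``assembled_copies`` of ``decoded`` copies, so
    ``length × (decoded − assembled) / assembled`` bases are missing.
    ``assembled_copies`` is 2 for a combined-diploid track, 1 for haploid.
    """
    if assembled_copies <= 0:
        raise ValueError("assembled_copies must be > 0")
    return float(sum(
        seg.interval.length * max(0, seg.copy_number - assembled_copies) / assembled_copies
        for seg in segments
    ))


def busco_depth_check(
    gene_intervals: dict[str, list[GenomicInterval]],
    tracks: dict[str, DepthTrack],
    mean_depth: float,
    threshold_fraction: float = 0.5,
) -> tuple[dict[str, str], float]:
    """Screen duplicated genes for spurious copies using mapped read depth.

    A duplicated gene passes when the mean depth over *every* annotated copy
    is at least ``threshold_fraction × mean_depth`` (a permissive bar chosen
    for recall); copies below it suggest a false duplication. Genes whose
    copies overlap no depth bins are reported "indeterminate" and excluded
    from the summary denominator. The summary is the passing percentage
    rounded to the nearest integer.
    """
    threshold = threshold_fraction * mean_depth
    status: dict[str, str] = {}
    for gene, copies in gene_intervals.items():
        means = []
        for iv in copies:
            track = tracks.get(iv.scaffold)
            if track is None:
                continue
            b0 = iv.start // track.bin_width
            b1 = max(b0 + 1, -(-iv.end // track.bin_width))
            window = track.counts[b0:min(b1, track.n_bins)]
            if len(window):
                means.append(float(window.mean()))
        if not means or len(means) < len(copies):
            status[gene] = "indeterminate"
            logger.warning("gene %s has copies with no depth bins; excluded", gene)
            continue
        status[gene] = "pass" if all(m >= threshold for m in means) else "fail"
    n_pass = sum(1 for s in status.values() if s == "pass")
    n_scored = sum(1 for s in status.values() if s != "indeterminate")
    percent = float(round(100.0 * n_pass / n_scored)) if n_scored else 0.0
    return status, percent


def summary_percent(n_passing: int, n_total: int) -> float:
    """Passing percentage rounded to the nearest integer (e.g. 285/439 -> 65)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return float(round(100.0 * n_passing / n_total))
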