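"""Two independent enrichment-peak callers and their consensus.

The first caller scores sliding windows against a genome-wide Poisson
background (MACS-style global lambda, transformed-p scores). The second
fits a two-component Poisson mixture to the bin counts by EM and calls
bins with high enriched-state posterior; it shares no statistics with the
first caller, which is the property the consensus step relies on.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .core import GenomicInterval, ScoredPeak
from .coverage import CoverageTrack
from .intervalops import MergedSet

__all__ = [
    "call_peaks_poisson",
    "call_peaks_posterior",
    "consensus",
    "score_from_p",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


def score_from_p(log_p: float, convention: str = "-10log10") -> float:
    """Transform a natural-log p-value into a peak score."""
    factor = {"-10log10": 10.0, "-log10": 1.0}[convention]
    return max(0.0, -factor * log_p / LN10)


def _merge_windows(starts: np.ndarray, ends: np.ndarray, max_gap: int):
    """Group sorted windows whose gaps are <= max_gap; yields index slices."""
    groups = []
    g_start = 0
    for i in range(1, len(starts)):
        if starts[i] - ends[i - 1] > max_gap:
            groups.append((g_start, i))
            g_start = i
    groups.append((g_start, len(starts)))
    return groups


def call_peaks_poisson(
    track: CoverageTrack,
    fraglen: int,
    p_threshold: float = 1e-3,
    score_convention: str = "-10log10",
    score_cap: float = 10000.0,
) -> list[ScoredPeak]:
    """Sliding-window Poisson caller with a genome-wide background rate.

    Windows of width ``fraglen`` (stepping one bin) are significant when
    the upper-tail Poisson probability P(X >= k | lambda = rate * fraglen)
    is below ``p_threshold``; significant windows within ``fraglen`` of
    each other merge into one peak. Score is the transformed p of the best
    window; summit is the center of the leftmost best window.
    """
    total_bp = track.genome_length
    if total_bp == 0 or track.library_total == 0:
        return []
    rate_per_bp = track.library_total / total_bp
    lam = rate_per_bp * fraglen
    w_bins = max(1, int(round(fraglen / track.bin_width)))
    peaks: list[ScoredPeak] = []
    for chrom, counts in track.counts.items():
        if len(counts) < w_bins:
            continue
        win = np.convolve(counts, np.ones(w_bins, dtype=np.int64), mode="valid")
        # P(X >= k) = sf(k - 1); computed in log space to keep tiny tails exact
        logp = poisson.logsf(win - 1, lam)
        sig = np.flatnonzero(logp < math.log(p_threshold))
        if sig.size == 0:
            continue
        bw = track.bin_width
        w_starts = sig * bw
        w_ends = w_starts + w_bins * bw
        for lo, hi in _merge_windows(w_starts, w_ends, max_gap=fraglen):
            idx = sig[lo:hi]
            seg_logp = logp[idx]
            best = int(np.argmin(seg_logp))  # leftmost minimum
            start = int(w_starts[lo])
            end = int(min(w_ends[hi - 1], track.chrom_sizes.get(chrom, w_ends[hi - 1])))
            summit_abs = int(idx[best] * bw + (w_bins * bw) // 2)
            summit = min(max(summit_abs - start, 0), end - start - 1)
            peaks.append(
                ScoredPeak(
                    GenomicInterval(chrom, start, end, name=f"pois_{chrom}_{start}"),
                    score=min(
                        score_from_p(float(seg_logp[best]), score_convention), score_cap
                    ),
                    summit=summit,
                    caller="poisson",
                )
            )
    return peaks


def _fit_poisson_mixture(counts: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """EM fit of a two-component Poisson mixture with deterministic
    moment-based initialization. Returns (lam_bg, lam_en, pi_en, posterior_en).
    """
    values, inverse, weights = np.unique(counts, return_inverse=True, return_counts=True)
    values = values.astype(float)
    w = weights.astype(float)
    n = w.sum()
    lam_bg = max(float(np.median(counts)), 0.1)
    hi = counts[counts >= np.quantile(counts, 0.95)]
    lam_en = max(float(hi.mean()) if hi.size else 2 * lam_bg, lam_bg + 0.1)
    pi_en = 0.05
    log_fact = gammaln(values + 1.0)
    prev_ll = -np.inf
    resp_en = None
    converged = False
    for _ in range(max_iter):
        log_bg = values * math.log(lam_bg) - lam_bg - log_fact + math.log1p(-pi_en)
        log_en = values * math.log(lam_en) - lam_en - log_fact + math.log(max(pi_en, 1e-300))
        log_norm = np.logaddexp(log_bg, log_en)
        ll = float(np.dot(w, log_norm))
        resp_en = np.exp(log_en - log_norm)
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
        w_en = w * resp_en
        w_bg = w - w_en
        pi_en = min(max(w_en.sum() / n, 1e-12), 1 - 1e-12)
        lam_en = max(np.dot(w_en, values) / max(w_en.sum(), 1e-300), 1e-6)
        lam_bg = max(np.dot(w_bg, values) / max(w_bg.sum(), 1e-300), 1e-6)
    if not converged:
        logger.warning("Poisson mixture EM did not converge; using best iterate")
    return lam_bg, lam_en, pi_en, resp_en[inverse]


def call_peaks_posterior(
    track: CoverageTrack,
    posterior_threshold: float = 0.5,
    min_fold: float = 2.0,
    score_cap: float = 1000.0,
) -> list[ScoredPeak]:
    """Mixture-posterior caller: the second, independent peak caller.

    Bin counts are modelled as a two-component Poisson mixture
    (background, enriched) fitted by EM with deterministic initialization;
    runs of bins with enriched-state posterior > 0.5 become peaks. The fit
    must separate the components (enriched mean >= ``min_fold`` x
    background mean) or no peaks are returned. Scores are
    -10*log10(1 - posterior), capped.
    """
    all_counts = np.concatenate(list(track.counts.values())) if track.counts else np.array([])
    if all_counts.size < 100:
        raise ValueError("posterior caller needs >= 100 bins")
    if np.all(all_counts == all_counts[0]):
        return []  # degenerate: no variation to separate components
    lam_bg, lam_en, _, post_all = _fit_poisson_mixture(all_counts)
    if lam_en < min_fold * lam_bg:
        return []
    peaks: list[ScoredPeak] = []
    offset = 0
    bw = track.bin_width
    for chrom, counts in track.counts.items():
        post = post_all[offset : offset + len(counts)]
        offset += len(counts)
        above = np.flatnonzero(post > posterior_threshold)
        if above.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(above) > 1)
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)), np.concatenate((breaks + 1, [above.size]))
        )
        for lo, hi in run_bounds:
            bins = above[lo:hi]
            start = int(bins[0] * bw)
            end = int(min((bins[-1] + 1) * bw, track.chrom_sizes.get(chrom, (bins[-1] + 1) * bw)))
            best = int(np.argmax(post[bins]))  # leftmost max posterior
            p_best = float(post[bins][best])
            tail = max(1.0 - p_best, 1e-300)
            score = min(-10.0 * math.log10(tail), score_cap)
            summit = min(max(int(bins[best] * bw + bw // 2) - start, 0), end - start - 1)
            peaks.append(
                ScoredPeak(
                    GenomicInterval(chrom, start, end, name=f"post_{chrom}_{start}"),
                    score=score,
                    summit=summit,
                    caller="posterior",
                )
            )
    return peaks


def consensus(
    peaks_a: list[ScoredPeak], peaks_b: list[ScoredPeak], min_overlap: int = 1
) -> list[ScoredPeak]:
    """Peaks of A confirmed by >= ``min_overlap`` bp overlap with any peak
    of B; A's coordinates and scores are kept."""
    if not peaks_a or not peaks_b:
        return []
    merged_b = MergedSet(p.interval for p in peaks_b)
    return [p for p in peaks_a if merged_b.overlap_bp(p.interval) >= min_overlap]
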