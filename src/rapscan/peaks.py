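"""SELEX peak calling: mate-pair filtering to RAP peaks.

The caller reproduces the genomic-SELEX peak-finding procedure: filtered
mate pairs are converted to per-base fragment coverage, maximal runs of
coverage at or above a read threshold become candidate regions, the region
signal is smoothed with a small normalized Gaussian kernel, a first
difference is taken, and peaks are the intervals between maximal ascending
and maximal descending derivative positions, 20-500 bases long (bounds
inclusive).

Pairing rule (declared, deterministic): within a derivative window take the
globally maximal positive difference as the ascending anchor (leftmost on
ties) and pair it with the most negative difference after it within the
maximum peak length (leftmost on ties). If the pair is valid, accept it and
recurse on the windows left and right of the peak; if the anchor has no
valid partner it is discarded and the search recurses on the windows
strictly left and right of the anchor position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    UNSTRANDED,
    ChromSizes,
    CoverageTrack,
    GenomicInterval,
    MatePair,
    PipelineConfig,
    RapPeak,
    log,
)

__all__ = [
    "FilterStats",
    "GaussianKernel",
    "CandidateRegion",
    "filter_mate_pairs",
    "fragment_coverage",
    "find_candidate_regions",
    "make_kernel",
    "smooth_region",
    "derivative",
    "pair_peaks",
    "call_raps",
]


@dataclass
class FilterStats:
    total: int = 0
    kept: int = 0
    cross_chromosome: int = 0
    span_too_short: int = 0
    span_too_long: int = 0


def filter_mate_pairs(
    pairs: Sequence[MatePair], min_span: int = 20, max_span: int = 500
) -> tuple[list[MatePair], FilterStats]:
    """Keep same-chromosome pairs whose 5'-end distance is within bounds (inclusive)."""
    stats = FilterStats(total=len(pairs))
    kept: list[MatePair] = []
    for p in pairs:
        if p.is_cross_chromosome:
            stats.cross_chromosome += 1
        elif p.span < min_span:
            stats.span_too_short += 1
        elif p.span > max_span:
            stats.span_too_long += 1
        else:
            kept.append(p)
    stats.kept = len(kept)
    return kept, stats


def fragment_coverage(
    pairs: Sequence[MatePair], chrom_sizes: ChromSizes, stranded: bool = True
) -> CoverageTrack:
    """Per-base fragment coverage: each pair covers [min(5' ends), max(5' ends)].

    Conservation: the track total equals the sum of fragment lengths
    (span + 1 bases per pair).
    """
    track = CoverageTrack(chrom_sizes, "fragment_coverage")
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in pairs:
        strand = p.strand if stranded else UNSTRANDED
        by_key.setdefault((p.chrom, strand), []).append((p.lo, p.hi))
    for (chrom, strand), spans in by_key.items():
        n = chrom_sizes.get(chrom)
        if n is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        arr = np.asarray(spans, dtype=np.int64)
        if (arr[:, 0] < 0).any() or (arr[:, 1] > n).any():
            raise ValueError(f"fragment coordinates beyond chromosome {chrom}")
        diff = np.zeros(n + 1, dtype=np.float64)
        np.add.at(diff, arr[:, 0], 1.0)
        np.add.at(diff, arr[:, 1], -1.0)
        vec = track.get(chrom, strand)
        vec += np.cumsum(diff[:-1])
    return track


@dataclass
class GaussianKernel:
    """A normalized symmetric Gaussian smoothing kernel."""

    window: int
    sigma: float
    taps: np.ndarray

    @property
    def half(self) -> int:
        return (self.window - 1) // 2


def make_kernel(window: int = 5, sigma: float = 1.0) -> GaussianKernel:
    if window < 1 or window % 2 != 1:
        raise ValueError("kernel window must be a positive odd integer")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    offsets = np.arange(window, dtype=np.float64) - (window - 1) / 2.0
    taps = np.exp(-(offsets**2) / (2.0 * sigma**2))
    taps /= taps.sum()
    return GaussianKernel(window, sigma, taps)


@dataclass
class CandidateRegion:
    """A maximal run of positions with raw coverage >= the region threshold.

    ``flanked`` is the raw signal extended by ``kernel.half`` bases on each
    side (edge-replicated at chromosome ends) so smoothing is defined over
    the whole region.
    """

    interval: GenomicInterval
    raw: np.ndarray
    flanked: np.ndarray = field(default_factory=lambda: np.empty(0))
    smoothed: np.ndarray = field(default_factory=lambda: np.empty(0))
    deriv: np.ndarray = field(default_factory=lambda: np.empty(0))


def find_candidate_regions(track: CoverageTrack, min_cov: float = 5) -> list[CandidateRegion]:
    """Maximal runs of consecutive positions with coverage >= ``min_cov``, per strand."""
    regions: list[CandidateRegion] = []
    for chrom, strand in track.keys():
        vec = track.get(chrom, strand)
        above = vec >= min_cov
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        bounds = np.concatenate(([0], edges + 1, [len(vec)]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            if above[s]:
                regions.append(
                    CandidateRegion(
                        GenomicInterval(chrom, int(s), int(e), strand),
                        raw=vec[s:e].copy(),
                    )
                )
    return regions


def _flanked_signal(vec: np.ndarray, start: int, end: int, half: int) -> np.ndarray:
    """Raw signal over [start - half, end + half), edge-replicated at chromosome ends."""
    lo = max(0, start - half)
    hi = min(len(vec), end + half)
    out = vec[lo:hi]
    pad_left = half - (start - lo)
    pad_right = half - (hi - end)
    if pad_left or pad_right:
        out = np.pad(out, (pad_left, pad_right), mode="edge")
    return out


def smooth_region(flanked: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Convolve the flanked raw signal with the normalized kernel.

    Input has ``kernel.half`` extra bases per side; output length equals the
    region length.
    """
    if len(flanked) < kernel.window:
        raise ValueError("flanked signal shorter than the kernel window")
    return np.convolve(flanked, kernel.taps, mode="valid")


def derivative(smoothed: np.ndarray) -> np.ndarray:
    """First difference d[i] = s[i+1] - s[i]; sum telescopes to s[-1] - s[0]."""
    return np.diff(smoothed)


def _pair_indices(
    d: np.ndarray, min_len: int = 20, max_len: int = 500
) -> list[tuple[int, int]]:
    """Apply the declared recursive pairing rule to a derivative vector.

    Returns (ascend_index, descend_index) pairs; the peak interval is
    [ascend_index, descend_index + 1) in region coordinates.
    """
    out: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(0, len(d))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        a = lo + int(np.argmax(d[lo:hi]))  # leftmost maximal ascent
        if d[a] <= 0:
            continue
        cap = min(hi, a + max_len)  # j <= a + max_len - 1 keeps length <= max_len
        j = -1
        if cap > a + 1:
            jj = a + 1 + int(np.argmin(d[a + 1 : cap]))  # leftmost minimal descent
            if d[jj] < 0:
                j = jj
        if j >= 0 and (j + 1 - a) >= min_len:
            out.append((a, j))
            stack.append((lo, a))
            stack.append((j + 1, hi))
        else:
            # anchor has no valid partner: discard it and split at the anchor
            stack.append((lo, a))
            stack.append((a + 1, hi))
    out.sort()
    return out


def pair_peaks(
    region: CandidateRegion, min_len: int = 20, max_len: int = 500
) -> list[RapPeak]:
    """Pair maximal ascending and descending derivative positions into peaks.

    Requires ``region.deriv`` (see :func:`call_raps` for the preparation
    steps); support statistics are left at zero here and populated by the
    caller.
    """
    if len(region.deriv) == 0:
        return []
    iv = region.interval
    peaks = []
    for a, j in _pair_indices(region.deriv, min_len, max_len):
        start = iv.start + a
        end = iv.start + j + 1
        peaks.append(
            RapPeak(
                GenomicInterval(iv.chrom, start, end, iv.strand),
                max_ascend_value=float(region.deriv[a]),
                max_descend_value=float(region.deriv[j]),
                peak_coverage=float(region.raw[a : j + 1].max()),
                support_reads=0,
            )
        )
    return peaks


def call_raps(
    pairs: Sequence[MatePair],
    chrom_sizes: ChromSizes,
    config: PipelineConfig | None = None,
) -> list[RapPeak]:
    """Full peak-calling pipeline from unfiltered mate pairs to sorted RAP peaks."""
    config = config or PipelineConfig()
    kept, stats = filter_mate_pairs(pairs, config.min_pair_span, config.max_pair_span)
    log.info(
        "filter_mate_pairs: total=%d kept=%d cross_chromosome=%d short=%d long=%d",
        stats.total,
        stats.kept,
        stats.cross_chromosome,
        stats.span_too_short,
        stats.span_too_long,
    )
    track = fragment_coverage(kept, chrom_sizes, stranded=config.stranded)
    kernel = make_kernel(config.kernel_window, config.kernel_sigma)
    regions = find_candidate_regions(track, config.min_region_coverage)
    log.info(
        "candidate regions: %d (min_cov=%s, kernel w=%d sigma=%g)",
        len(regions),
        config.min_region_coverage,
        config.kernel_window,
        config.kernel_sigma,
    )

    # sorted fragment bounds per (chrom, strand) for support_reads counting
    frag_lo: dict[tuple[str, str], np.ndarray] = {}
    frag_hi: dict[tuple[str, str], np.ndarray] = {}
    for p in kept:
        strand = p.strand if config.stranded else UNSTRANDED
        frag_lo.setdefault((p.chrom, strand), []).append(p.lo)  # type: ignore[union-attr]
        frag_hi.setdefault((p.chrom, strand), []).append(p.hi)  # type: ignore[union-attr]
    for key in frag_lo:
        frag_lo[key] = np.sort(np.asarray(frag_lo[key], dtype=np.int64))
        frag_hi[key] = np.sort(np.asarray(frag_hi[key], dtype=np.int64))

    peaks: list[RapPeak] = []
    for region in regions:
        iv = region.interval
        vec = track.get(iv.chrom, iv.strand)
        region.flanked = _flanked_signal(vec, iv.start, iv.end, kernel.half)
        region.smoothed = smooth_region(region.flanked, kernel)
        region.deriv = derivative(region.smoothed)
        for pk in pair_peaks(region, config.min_peak_len, config.max_peak_len):
            key = (iv.chrom, iv.strand)
            lo_arr = frag_lo.get(key)
            support = 0
            if lo_arr is not None:
                hi_arr = frag_hi[key]
                n = len(lo_arr)
                # fragments with lo < peak.end and hi > peak.start
                support = int(
                    n
                    - np.searchsorted(hi_arr, pk.interval.start, side="right")
                    - (n - np.searchsorted(lo_arr, pk.interval.end, side="left"))
                )
            peaks.append(
                RapPeak(
                    pk.interval,
                    pk.max_ascend_value,
                    pk.max_descend_value,
                    pk.peak_coverage,
                    support_reads=support,
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.strand))
    peaks = [
        RapPeak(
            p.interval,
            p.max_ascend_value,
            p.max_descend_value,
            p.peak_coverage,
            p.support_reads,
            name=f"RAP{i + 1:05d}",
        )
        for i, p in enumerate(peaks)
    ]
    log.info("called %d peaks", len(peaks))
    return peaks
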