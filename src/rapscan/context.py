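"""Genomic context of RAPs: classification and feature-class enrichment.

A RAP is sense if it shares at least one base with a gene on its own strand,
antisense if it overlaps genes only on the opposite strand, intergenic
otherwise (sense takes precedence). Feature-class enrichment is tested
against a length-preserving randomization null: each RAP keeps its length
and is re-placed uniformly over the two-stranded genome, and the observed
per-class RAP count is compared with the randomized distribution.

Overlap counting is strand-aware: a stranded feature is only hit by a RAP
on the same strand, an unstranded feature by RAPs on either strand. This is
what lets the two telomeric-repeat strands (the silent CA-rich strand and
the transcribed GU-rich TERRA strand) carry distinct enrichment signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    MINUS,
    PLUS,
    UNSTRANDED,
    ChromSizes,
    Feature,
    GenomicInterval,
    RapPeak,
    log,
    rng_from_seed,
)

__all__ = [
    "SENSE",
    "ANTISENSE",
    "INTERGENIC",
    "EnrichmentResult",
    "classify_raps",
    "genome_class_background",
    "count_feature_overlaps",
    "randomize_rap_locations",
    "enrichment_test",
]

SENSE = "sense"
ANTISENSE = "antisense"
INTERGENIC = "intergenic"

DEFAULT_GENE_CLASSES = ("ORF", "gene")


def _as_interval(obj) -> GenomicInterval:
    return obj.interval if isinstance(obj, (RapPeak, Feature)) else obj


class _MergedIntervals:
    """Merged, sorted intervals on one (chrom, strand) supporting vectorized
    any-overlap queries via searchsorted."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        ivs = sorted(intervals)
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)

    def overlaps(self, qstart: np.ndarray, qend: np.ndarray) -> np.ndarray:
        """Boolean vector: does each query [qstart, qend) hit any interval?"""
        if len(self.starts) == 0:
            return np.zeros(len(np.atleast_1d(qstart)), dtype=bool)
        j = np.searchsorted(self.ends, qstart, side="right")
        hit = j < len(self.starts)
        safe = np.minimum(j, len(self.starts) - 1)
        return hit & (self.starts[safe] < qend)


class _StrandedIndex:
    """Per-(chrom, strand) merged-interval index over a feature subset.

    Unstranded features are registered on both strands.
    """

    def __init__(self, features: Iterable[Feature]):
        raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for f in features:
            iv = f.interval
            strands = (PLUS, MINUS) if iv.strand == UNSTRANDED else (iv.strand,)
            for s in strands:
                raw.setdefault((iv.chrom, s), []).append((iv.start, iv.end))
        self._idx = {key: _MergedIntervals(vals) for key, vals in raw.items()}

    def overlaps_one(self, iv: GenomicInterval) -> bool:
        strands = (PLUS, MINUS) if iv.strand == UNSTRANDED else (iv.strand,)
        for s in strands:
            m = self._idx.get((iv.chrom, s))
            if m is not None and bool(
                m.overlaps(np.asarray([iv.start]), np.asarray([iv.end]))[0]
            ):
                return True
        return False

    def get(self, chrom: str, strand: str) -> _MergedIntervals | None:
        return self._idx.get((chrom, strand))


def classify_raps(
    raps: Sequence[RapPeak | GenomicInterval],
    features: Sequence[Feature],
    gene_classes: Sequence[str] = DEFAULT_GENE_CLASSES,
) -> tuple[list[str], dict[str, float]]:
    """Assign each RAP exactly one of sense/antisense/intergenic.

    Returns the per-RAP class list (same order as input) and the class
    fractions, which sum to 1.
    """
    genes = [f for f in features if f.feature_class in gene_classes]
    same = _StrandedIndex(genes)
    classes: list[str] = []
    for rap in raps:
        iv = _as_interval(rap)
        if iv.strand == UNSTRANDED:
            if same.overlaps_one(iv):
                log.warning("unstranded RAP %s overlaps a gene; classified sense", iv)
                classes.append(SENSE)
            else:
                classes.append(INTERGENIC)
            continue
        opp = MINUS if iv.strand == PLUS else PLUS
        if same.overlaps_one(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand)):
            classes.append(SENSE)
        elif same.overlaps_one(GenomicInterval(iv.chrom, iv.start, iv.end, opp)):
            classes.append(ANTISENSE)
        else:
            classes.append(INTERGENIC)
    n = max(1, len(classes))
    fractions = {
        c: classes.count(c) / n for c in (SENSE, ANTISENSE, INTERGENIC)
    }
    return classes, fractions


def genome_class_background(
    features: Sequence[Feature],
    chrom_sizes: ChromSizes,
    gene_classes: Sequence[str] = DEFAULT_GENE_CLASSES,
) -> dict[str, float]:
    """Fractions of two-stranded position space that are sense-genic,
    antisense-genic and intergenic (sense precedence, as for RAPs)."""
    genes = [f for f in features if f.feature_class in gene_classes]
    sense_n = antisense_n = 0
    total = 2 * chrom_sizes.total_length
    for chrom, length in chrom_sizes.items():
        cover = {PLUS: np.zeros(length, dtype=bool), MINUS: np.zeros(length, dtype=bool)}
        for f in genes:
            iv = f.interval
            if iv.chrom != chrom:
                continue
            strands = (PLUS, MINUS) if iv.strand == UNSTRANDED else (iv.strand,)
            for s in strands:
                cover[s][iv.start : iv.end] = True
        sense_n += int(cover[PLUS].sum()) + int(cover[MINUS].sum())
        antisense_n += int((cover[MINUS] & ~cover[PLUS]).sum())
        antisense_n += int((cover[PLUS] & ~cover[MINUS]).sum())
    return {
        SENSE: sense_n / total,
        ANTISENSE: antisense_n / total,
        INTERGENIC: (total - sense_n - antisense_n) / total,
    }


def count_feature_overlaps(
    raps: Sequence[RapPeak | GenomicInterval],
    features: Sequence[Feature],
    classes: Sequence[str] | None = None,
) -> dict[str, int]:
    """Number of RAPs overlapping (>= 1 base, strand-aware) each feature class.

    A RAP may count toward several classes; within one class it counts once
    however many features it touches.
    """
    if classes is None:
        classes = sorted({f.feature_class for f in features})
    ivs = [_as_interval(r) for r in raps]
    counts: dict[str, int] = {}
    for cls in classes:
        idx = _StrandedIndex(f for f in features if f.feature_class == cls)
        counts[cls] = sum(1 for iv in ivs if idx.overlaps_one(iv))
    return counts


def _admissible_layout(
    chrom_sizes: ChromSizes, length: int
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Admissible start counts per (strand, chrom) for a RAP of given length."""
    names = list(chrom_sizes)
    per_chrom = np.asarray(
        [max(0, chrom_sizes[c] - length + 1) for c in names], dtype=np.int64
    )
    counts = np.concatenate([per_chrom, per_chrom])  # + strand block, - strand block
    return counts, names, per_chrom


def _randomize_many(
    lengths: Sequence[int],
    chrom_sizes: ChromSizes,
    rng: np.random.Generator,
    n_sets: int,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """For each RAP length, draw ``n_sets`` uniform placements.

    Returns one (chrom_index, strand_index, start) triple of arrays per RAP.
    Placement is uniform over every admissible (chromosome, strand, start)
    position, so chromosomes are weighted by their admissible length and no
    placement overhangs a chromosome end.
    """
    out = []
    for length in lengths:
        counts, names, per_chrom = _admissible_layout(chrom_sizes, int(length))
        total = int(counts.sum())
        if total == 0:
            raise ValueError(f"no chromosome can host a RAP of length {length}")
        u = rng.integers(0, total, size=n_sets)
        cum = np.cumsum(counts)
        slot = np.searchsorted(cum, u, side="right")
        offset = u - (cum[slot] - counts[slot])
        strand_idx = (slot >= len(names)).astype(np.int8)
        chrom_idx = slot % len(names)
        out.append((chrom_idx, strand_idx, offset))
    return out


def randomize_rap_locations(
    raps: Sequence[RapPeak | GenomicInterval],
    chrom_sizes: ChromSizes,
    seed: int | np.random.Generator,
) -> list[GenomicInterval]:
    """One randomized RAP set: lengths preserved, placement uniform over the
    two-stranded genome."""
    rng = seed if isinstance(seed, np.random.Generator) else rng_from_seed(seed)
    lengths = [_as_interval(r).length for r in raps]
    names = list(chrom_sizes)
    draws = _randomize_many(lengths, chrom_sizes, rng, 1)
    placed = []
    for length, (ci, si, st) in zip(lengths, draws):
        strand = PLUS if si[0] == 0 else MINUS
        chrom = names[int(ci[0])]
        start = int(st[0])
        placed.append(GenomicInterval(chrom, start, start + length, strand))
    return placed


@dataclass
class EnrichmentResult:
    """Observed vs randomized-expected RAP count for one feature class.

    ``p_enrich``/``p_deplete`` are the +1-corrected one-tailed empirical
    p-values; ``p`` is the smaller tail and ``direction`` names it.
    """

    feature_class: str
    observed: int
    expected_mean: float
    enrichment: float
    log2_enrichment: float
    p_enrich: float
    p_deplete: float
    p: float
    direction: str
    n_boot: int


def enrichment_test(
    raps: Sequence[RapPeak | GenomicInterval],
    features: Sequence[Feature],
    chrom_sizes: ChromSizes,
    classes: Sequence[str] | None = None,
    n_boot: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> list[EnrichmentResult]:
    """Length-preserving randomization test of per-class RAP counts."""
    if n_boot <= 0:
        raise ValueError("no randomizations (n_boot must be positive)")
    if classes is None:
        classes = sorted({f.feature_class for f in features})
    observed = count_feature_overlaps(raps, features, classes)
    lengths = [_as_interval(r).length for r in raps]
    names = list(chrom_sizes)
    rng = rng_from_seed(seed)
    indices = {cls: _StrandedIndex(f for f in features if f.feature_class == cls) for cls in classes}

    boot_counts = {cls: np.zeros(n_boot, dtype=np.int64) for cls in classes}
    done = 0
    while done < n_boot:
        size = min(chunk, n_boot - done)
        draws = _randomize_many(lengths, chrom_sizes, rng, size)
        for (ci, si, st), length in zip(draws, lengths):
            qend = st + length
            for cls in classes:
                idx = indices[cls]
                hit = np.zeros(size, dtype=bool)
                for c_i, cname in enumerate(names):
                    for s_i, strand in enumerate((PLUS, MINUS)):
                        m = idx.get(cname, strand)
                        if m is None:
                            continue
                        sel = (ci == c_i) & (si == s_i)
                        if sel.any():
                            hit[sel] |= m.overlaps(st[sel], qend[sel])
                boot_counts[cls][done : done + size] += hit
        done += size

    results = []
    for cls in classes:
        counts = boot_counts[cls]
        obs = observed[cls]
        mean = float(counts.mean())
        p_enr = (1 + int((counts >= obs).sum())) / (n_boot + 1)
        p_dep = (1 + int((counts <= obs).sum())) / (n_boot + 1)
        if mean == 0.0:
            enr = float("inf") if obs > 0 else float("nan")
            p_enr = 1.0 / (n_boot + 1) if obs > 0 else p_enr
        else:
            enr = obs / mean
        with np.errstate(divide="ignore"):
            l2 = float(np.log2(enr)) if enr == enr else float("nan")
        direction = "enrichment" if p_enr <= p_dep else "depletion"
        results.append(
            EnrichmentResult(
                feature_class=cls,
                observed=obs,
                expected_mean=mean,
                enrichment=enr,
                log2_enrichment=l2,
                p_enrich=p_enr,
                p_deplete=p_dep,
                p=min(p_enr, p_dep),
                direction=direction,
                n_boot=n_boot,
            )
        )
    return results
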