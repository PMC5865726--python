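"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* an annotated genome with non-overlapping genes, telomere tracts carrying
  (C1-3A)n repeats on the silent CA-rich strand, and a handful of auxiliary
  feature classes;
* a SELEX mate-pair library of 30-400 nt fragments: a uniform background
  plus planted fragments straddling each true RAP so that the RAP's mean
  per-base coverage is its enrichment fold times the background level;
* a log-normal TPM table with RAP-host assignment odds elevated in a chosen
  TPM segment;
* strand-specific Pol II read-end tracks with a 5'-proximal peak, a smooth
  decline toward the 3' end, Poisson count noise and a multiplicative step
  drop downstream of each planted RAP.

Every generator is a pure function of its spec and seed; the planted truth
is serializable to JSON so tests can join pipeline output to it by id.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    MINUS,
    PLUS,
    ChromSizes,
    CoverageTrack,
    Feature,
    GenomicInterval,
    MatePair,
    log,
    rng_from_seed,
)

__all__ = [
    "SimGenomeSpec",
    "SimTruth",
    "telomere_repeat_string",
    "simulate_genome",
    "plant_raps",
    "simulate_selex",
    "expected_background_coverage",
    "simulate_expression",
    "simulate_occupancy",
]


@dataclass
class SimGenomeSpec:
    """Layout parameters for the synthetic annotated genome."""

    chrom_lengths: tuple[int, ...] = (500_000, 500_000)
    n_genes: int = 200
    gene_len_log_mean: float = math.log(1400.0)
    gene_len_log_sigma: float = 0.45
    gene_len_range: tuple[int, int] = (500, 4000)
    strand_prob: float = 0.5
    min_intergenic_gap: int = 100
    telomere_len: int = 300
    n_trna: int = 8
    n_snorna: int = 4
    n_ars: int = 4
    n_ltr: int = 4
    seed: int = 0


_AUX_LENGTHS = {
    "tRNA": (70, 90),
    "snoRNA": (100, 300),
    "ARS": (100, 200),
    "LTR": (250, 350),
}


def telomere_repeat_string(length: int, rng: np.random.Generator) -> str:
    """A (C1-3A)n repeat string of exactly ``length`` nt (length >= 2)."""
    if length < 2:
        raise ValueError("telomere repeat needs length >= 2")
    parts: list[str] = []
    remaining = length
    while remaining > 0:
        ks = [k for k in (1, 2, 3) if k <= remaining - 1 and k != remaining - 2]
        k = int(rng.choice(ks))
        parts.append("C" * k + "A")
        remaining -= k + 1
    return "".join(parts)


def simulate_genome(spec: SimGenomeSpec) -> tuple[ChromSizes, list[Feature]]:
    """Generate chromosome sizes and a non-overlapping feature annotation.

    Telomere tracts at both chromosome ends are emitted as unstranded
    ``telomere`` features plus a stranded ``telomeric_repeat`` feature on the
    CA-rich strand (declared convention: + at the left end, - at the right
    end). Exactly ``n_genes`` ORF features are placed; an error is raised if
    they do not fit.
    """
    rng = rng_from_seed(spec.seed, 1)
    names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    sizes = ChromSizes(dict(zip(names, spec.chrom_lengths)))
    features: list[Feature] = []
    for name, n in sizes.items():
        if n < 2 * spec.telomere_len + 1000:
            raise ValueError(f"chromosome {name} too short for telomere tracts")
        features.append(
            Feature(GenomicInterval(name, 0, spec.telomere_len, "."), "telomere", f"TEL_{name}_L")
        )
        features.append(
            Feature(
                GenomicInterval(name, n - spec.telomere_len, n, "."),
                "telomere",
                f"TEL_{name}_R",
            )
        )
        features.append(
            Feature(
                GenomicInterval(name, 0, spec.telomere_len, PLUS),
                "telomeric_repeat",
                f"TELREP_{name}_L",
            )
        )
        features.append(
            Feature(
                GenomicInterval(name, n - spec.telomere_len, n, MINUS),
                "telomeric_repeat",
                f"TELREP_{name}_R",
            )
        )

    queue = (
        ["ORF"] * spec.n_genes
        + ["tRNA"] * spec.n_trna
        + ["snoRNA"] * spec.n_snorna
        + ["ARS"] * spec.n_ars
        + ["LTR"] * spec.n_ltr
    )
    rng.shuffle(queue)
    counters: dict[str, int] = {}
    qi = 0
    for name, n in sizes.items():
        cursor = spec.telomere_len + spec.min_intergenic_gap
        limit = n - spec.telomere_len - spec.min_intergenic_gap
        while qi < len(queue):
            cls = queue[qi]
            if cls == "ORF":
                length = int(
                    np.clip(
                        rng.lognormal(spec.gene_len_log_mean, spec.gene_len_log_sigma),
                        *spec.gene_len_range,
                    )
                )
            else:
                lo, hi = _AUX_LENGTHS[cls]
                length = int(rng.integers(lo, hi + 1))
            if cursor + length > limit:
                break
            strand = PLUS if rng.random() < spec.strand_prob else MINUS
            counters[cls] = counters.get(cls, 0) + 1
            fid = f"{cls}_{counters[cls]:04d}" if cls != "ORF" else f"gene_{counters[cls]:04d}"
            features.append(Feature(GenomicInterval(name, cursor, cursor + length, strand), cls, fid))
            cursor += length + spec.min_intergenic_gap + int(rng.integers(0, 201))
            qi += 1
        if qi >= len(queue):
            break
    if qi < len(queue):
        raise ValueError(
            f"genome too small: placed {qi} of {len(queue)} requested features"
        )
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.interval.strand))
    return sizes, features


@dataclass
class SimTruth:
    """Planted ground truth joining all generators."""

    raps: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    fold: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    rap_to_gene: dict[str, str] = field(default_factory=dict)
    segment_odds: float = 1.0

    def rap_ids(self) -> list[str]:
        return [rid for rid, _ in self.raps]

    def to_json(self, path: str | Path) -> None:
        data = {
            "raps": [
                {
                    "id": rid,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "strand": iv.strand,
                    "fold": self.fold.get(rid, 1.0),
                    "delta": self.delta.get(rid, 0.0),
                    "gene": self.rap_to_gene.get(rid, ""),
                }
                for rid, iv in self.raps
            ],
            "segment_odds": self.segment_odds,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            data = json.load(fh)
        truth = cls(segment_odds=data.get("segment_odds", 1.0))
        for r in data["raps"]:
            iv = GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"])
            truth.raps.append((r["id"], iv))
            truth.fold[r["id"]] = r["fold"]
            truth.delta[r["id"]] = r["delta"]
            if r["gene"]:
                truth.rap_to_gene[r["id"]] = r["gene"]
        return truth


def plant_raps(
    features: Sequence[Feature],
    n_raps: int = 30,
    rap_len_range: tuple[int, int] = (100, 250),
    fold: float = 20.0,
    delta: float = 0.4,
    rel_pos_range: tuple[float, float] = (0.2, 0.7),
    trim: int = 200,
    seed: int = 0,
) -> SimTruth:
    """Plant RAPs inside trimmed gene bodies on the host gene's strand.

    Host genes are sampled without replacement among genes whose trimmed body
    leaves >= 20 nt up- and downstream of the RAP; the RAP start sits at a
    uniform relative position within the admissible window.
    """
    if not 0 <= delta < 1:
        raise ValueError("delta must be in [0, 1)")
    rng = rng_from_seed(seed, 2)
    genes = [f for f in features if f.feature_class == "ORF"]
    max_len = rap_len_range[1]
    eligible = [g for g in genes if g.interval.length - 2 * trim >= max_len + 40]
    if len(eligible) < n_raps:
        raise ValueError(
            f"only {len(eligible)} genes can host a RAP of length {max_len}"
        )
    hosts = [eligible[i] for i in rng.choice(len(eligible), n_raps, replace=False)]
    truth = SimTruth()
    for i, gene in enumerate(hosts):
        giv = gene.interval
        length = int(rng.integers(rap_len_range[0], rap_len_range[1] + 1))
        body = giv.length - 2 * trim
        lo_f, hi_f = rel_pos_range
        window = body - length - 40  # keep >= 20 nt on both sides
        rel = lo_f + (hi_f - lo_f) * rng.random()
        off = 20 + int(round(rel * window))
        if giv.strand == MINUS:
            start = giv.end - trim - off - length
        else:
            start = giv.start + trim + off
        rid = f"trueRAP{i + 1:03d}"
        iv = GenomicInterval(giv.chrom, start, start + length, giv.strand)
        truth.raps.append((rid, iv))
        truth.fold[rid] = fold
        truth.delta[rid] = delta
        truth.rap_to_gene[rid] = gene.feature_id
    return truth


def _mean_fragment_bases(frag_len_range: tuple[int, int]) -> float:
    # fragment of length l covers l bases; lengths uniform on integers
    return (frag_len_range[0] + frag_len_range[1]) / 2.0


def expected_background_coverage(
    n_pairs: int,
    chrom_sizes: ChromSizes,
    truth: SimTruth,
    frag_len_range: tuple[int, int] = (30, 400),
) -> float:
    """Expected uniform background coverage per strand-base for a library of
    ``n_pairs`` built by :func:`simulate_selex` with this truth."""
    g2 = 2 * chrom_sizes.total_length
    kappa = _mean_fragment_bases(frag_len_range) / g2
    s = sum(max(0.0, f - 1.0) for f in truth.fold.values())
    n_bg = n_pairs / (1.0 + kappa * s)
    return n_bg * kappa


def simulate_selex(
    chrom_sizes: ChromSizes,
    truth: SimTruth,
    n_pairs: int = 200_000,
    frag_len_range: tuple[int, int] = (30, 400),
    jitter: int = 20,
    seed: int = 0,
) -> list[MatePair]:
    """A shuffled SELEX mate-pair library with planted enrichment.

    Background fragments start uniformly over the two-stranded genome with
    lengths uniform in ``frag_len_range``. Planted fragments straddle their
    RAP tightly: each overhangs the RAP boundaries by an independent
    geometric 0..``jitter`` nt on each side (late-round SELEX pools bracket
    the binding region closely, so short overhangs dominate), which makes
    fragment coverage rise and fall most steeply exactly at the RAP edges. Planted counts are sized so the expected per-base
    coverage over a RAP is ``fold`` times the background level.
    """
    rng = rng_from_seed(seed, 3)
    lmin, lmax = frag_len_range
    names = list(chrom_sizes)
    lengths_arr = np.asarray([chrom_sizes[c] for c in names], dtype=np.float64)
    g2 = 2 * chrom_sizes.total_length
    kappa = _mean_fragment_bases(frag_len_range) / g2
    excess = np.asarray([max(0.0, truth.fold[rid] - 1.0) for rid, _ in truth.raps])
    s = float(excess.sum())
    n_bg = int(round(n_pairs / (1.0 + kappa * s)))
    n_planted_total = n_pairs - n_bg
    pairs: list[MatePair] = []

    # background
    frag_len = rng.integers(lmin, lmax + 1, size=n_bg)
    chrom_idx = rng.choice(len(names), size=n_bg, p=lengths_arr / lengths_arr.sum())
    strands = rng.integers(0, 2, size=n_bg)
    chrom_len = lengths_arr[chrom_idx]
    starts = np.floor(rng.random(n_bg) * (chrom_len - frag_len)).astype(np.int64)
    for i in range(n_bg):
        a, b = int(starts[i]), int(starts[i] + frag_len[i] - 1)
        st = PLUS if strands[i] == 0 else MINUS
        if st == MINUS:
            a, b = b, a
        pairs.append(MatePair(names[int(chrom_idx[i])], a, b, st))

    # planted
    if n_planted_total > 0 and s > 0:
        counts = rng.multinomial(n_planted_total, excess / s)
        for (rid, iv), n_i in zip(truth.raps, counts):
            chrom_n = chrom_sizes[iv.chrom]
            for _ in range(int(n_i)):
                if iv.length + 2 * jitter <= lmax:
                    # overhang mode at 0: the coverage derivative peaks at the boundary
                    left = min(int(rng.geometric(0.15)) - 1, jitter)
                    right = min(int(rng.geometric(0.15)) - 1, jitter)
                    fl = iv.length + left + right
                    start = iv.start - left
                elif iv.length <= lmax:
                    fl = int(rng.integers(max(lmin, iv.length), lmax + 1))
                    over = int(rng.integers(0, fl - iv.length + 1))
                    start = iv.start - over
                else:
                    fl = int(rng.integers(lmin, lmax + 1))
                    start = int(rng.integers(iv.start - fl + 1, iv.end))
                start = max(0, min(start, chrom_n - fl))
                a, b = start, start + fl - 1
                if iv.strand == MINUS:
                    a, b = b, a
                pairs.append(MatePair(iv.chrom, a, b, iv.strand))

    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def simulate_expression(
    features: Sequence[Feature],
    n_rap_genes: int = 200,
    odds: float = 1.0,
    segment_bounds: tuple[float, ...] = (1.0, 30.0, 80.0),
    tpm_log_mean: float = 3.0,
    tpm_log_sigma: float = 2.0,
    odds_segment: int = 1,
    seed: int = 0,
) -> tuple[list[tuple[str, float]], set[str]]:
    """A log-normal TPM table plus a RAP-host gene assignment.

    Assignment is a weighted draw without replacement; genes in segment
    ``odds_segment`` (default the second segment, (1, 30]) have their
    selection weight multiplied by ``odds``. ``odds = 1`` gives the
    TPM-independent null.
    """
    rng = rng_from_seed(seed, 4)
    gids = [f.feature_id for f in features if f.feature_class == "ORF"]
    if n_rap_genes > len(gids):
        raise ValueError("more RAP genes requested than genes available")
    tpm = rng.lognormal(tpm_log_mean, tpm_log_sigma, size=len(gids))
    edges = [0.0, *segment_bounds, math.inf]
    lo, hi = edges[odds_segment], edges[odds_segment + 1]
    w = np.where((tpm > lo) & (tpm <= hi), float(odds), 1.0)
    pick = rng.choice(len(gids), size=n_rap_genes, replace=False, p=w / w.sum())
    rap_genes = {gids[i] for i in pick}
    return list(zip(gids, tpm.tolist())), rap_genes


def simulate_occupancy(
    features: Sequence[Feature],
    chrom_sizes: ChromSizes,
    truth: SimTruth,
    mean_density: float = 0.2,
    fiveprime_boost: float = 2.0,
    threeprime_end_frac: float = 0.6,
    peak_len: int = 200,
    seed: int = 0,
) -> CoverageTrack:
    """Strand-specific Pol II read-end tracks with planted occupancy drops.

    Per-base expected density along each gene (5'->3'): ``mean_density``
    times ``fiveprime_boost`` within the first ``peak_len`` nt, then an
    exponential decline reaching ``threeprime_end_frac`` of the post-peak
    level at the gene end, times ``1 - delta`` downstream of a planted RAP's
    end on its host gene. Realized counts are Poisson; intergenic signal
    is zero.
    """
    rng = rng_from_seed(seed, 5)
    track = CoverageTrack(chrom_sizes, "read_end_counts")
    gene_delta: dict[str, tuple[int, float]] = {}
    by_id = {f.feature_id: f for f in features}
    for rid, iv in truth.raps:
        gid = truth.rap_to_gene.get(rid)
        if not gid or gid not in by_id:
            continue
        gene = by_id[gid]
        giv = gene.interval
        re_oriented = (
            giv.end - iv.start if giv.strand == MINUS else iv.end - giv.start
        )
        gene_delta[gid] = (re_oriented, truth.delta.get(rid, 0.0))
    for f in features:
        if f.feature_class != "ORF":
            continue
        giv = f.interval
        n = giv.length
        x = np.arange(n, dtype=np.float64)
        mu = np.full(n, mean_density)
        head = x < peak_len
        mu[head] *= fiveprime_boost
        if n > peak_len + 1 and threeprime_end_frac != 1.0:
            frac = (x[~head] - peak_len) / (n - 1 - peak_len)
            mu[~head] *= np.power(threeprime_end_frac, frac)
        if f.feature_id in gene_delta:
            re_o, delta = gene_delta[f.feature_id]
            mu[int(re_o) :] *= 1.0 - delta
        counts = rng.poisson(mu).astype(np.float64)
        if giv.strand == MINUS:
            counts = counts[::-1]
        vec = track.get(giv.chrom, giv.strand)
        vec[giv.start : giv.end] += counts
    # make sure both strand tracks exist even if one is empty
    for chrom in chrom_sizes:
        track.get(chrom, PLUS)
        track.get(chrom, MINUS)
    return track
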