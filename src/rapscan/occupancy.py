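"""RNA Pol II occupancy around RAPs from strand-specific read-end tracks.

Two complementary views:

* a gene-centred decile view: the gene body minus 200 nt at each end (the
  5'-proximal polymerase peak and, for symmetry, the 3' end) is split into
  10 equal segments; for each boundary d = 1..9 the log2 ratio of mean
  density over deciles 1..d to deciles d+1..10 is computed, and the ratio
  samples from RAP-harboring and RAP-free segments are compared;

* a RAP-centred call: read-end counts upstream (trimmed gene start to RAP
  start) and downstream (RAP end to trimmed gene end) are compared with the
  exact conditional test for two Poisson rates (binomial on the total with
  success probability L_up / (L_up + L_down)); the up/down log2 density
  ratio is reported only when significant at alpha, otherwise recorded as 0,
  and each RAP is re-placed on background genes at the same relative
  position to build the expected call distribution, compared by chi-squared
  on categories and Kolmogorov-Smirnov on the log2-ratio samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    MINUS,
    UNSTRANDED,
    CoverageTrack,
    Feature,
    GenomicInterval,
    RapPeak,
    log,
    rng_from_seed,
)

__all__ = [
    "DecileProfile",
    "UpDownCall",
    "BackgroundComparison",
    "gene_signal",
    "decile_profile",
    "decile_profiles",
    "decile_updown_distribution",
    "rap_updown_test",
    "rap_updown_tests",
    "randomized_background",
    "compare_to_background",
]

INCREASE = "increase"
DECREASE = "decrease"
NOCHANGE = "nochange"
CATEGORIES = (INCREASE, DECREASE, NOCHANGE)


def gene_signal(track: CoverageTrack, gene: Feature) -> np.ndarray:
    """Per-base signal over the gene, oriented 5' -> 3' on the gene's strand."""
    iv = gene.interval
    vec = track.get(iv.chrom, iv.strand)[iv.start : iv.end]
    if iv.strand == MINUS:
        vec = vec[::-1]
    return vec


@dataclass
class DecileProfile:
    gene_id: str
    densities: np.ndarray  # read ends per position, 10 values, 5'->3'
    body: GenomicInterval  # trimmed gene body (genomic coordinates)


def _decile_bounds(length: int, n: int = 10) -> np.ndarray:
    # segment boundaries by rounding cumulative tenths
    return np.asarray([round(i * length / n) for i in range(n + 1)], dtype=np.int64)


def decile_profile(
    gene: Feature, track: CoverageTrack, trim: int = 200, n_deciles: int = 10
) -> DecileProfile:
    """Mean read-end density per equal segment of the trimmed gene body.

    Raises ``ValueError`` for genes whose trimmed body is shorter than
    200 nt (i.e. gene length < 2 * trim + 200); callers exclude and log.
    """
    iv = gene.interval
    body_len = iv.length - 2 * trim
    if body_len < 200:
        raise ValueError(
            f"gene {gene.feature_id} trimmed body {body_len} nt < 200 nt"
        )
    sig = gene_signal(track, gene)[trim : trim + body_len]
    bounds = _decile_bounds(body_len, n_deciles)
    dens = np.array(
        [sig[bounds[i] : bounds[i + 1]].sum() / (bounds[i + 1] - bounds[i]) for i in range(n_deciles)]
    )
    body = GenomicInterval(iv.chrom, iv.start + trim, iv.end - trim, iv.strand)
    return DecileProfile(gene.feature_id, dens, body)


def decile_profiles(
    genes: Sequence[Feature], track: CoverageTrack, trim: int = 200
) -> tuple[list[DecileProfile], list[tuple[str, str]]]:
    """Profiles for all eligible genes plus (gene_id, reason) exclusions."""
    profiles, excluded = [], []
    for g in genes:
        try:
            profiles.append(decile_profile(g, track, trim))
        except ValueError as exc:
            excluded.append((g.feature_id, str(exc)))
    if excluded:
        log.info("decile_profiles: excluded %d short genes", len(excluded))
    return profiles, excluded


def _decile_genomic_interval(gene: Feature, trim: int, d: int, n: int = 10) -> GenomicInterval:
    """Genomic interval of transcription-order decile ``d`` (1-based)."""
    iv = gene.interval
    body_len = iv.length - 2 * trim
    bounds = _decile_bounds(body_len, n)
    lo, hi = int(bounds[d - 1]), int(bounds[d])
    if iv.strand == MINUS:
        start = iv.end - trim - hi
        end = iv.end - trim - lo
    else:
        start = iv.start + trim + lo
        end = iv.start + trim + hi
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def decile_updown_distribution(
    genes: Sequence[Feature],
    raps: Sequence[RapPeak | GenomicInterval],
    track: CoverageTrack,
    trim: int = 200,
) -> pd.DataFrame:
    """Per-boundary log2 up/down density ratios, split by RAP harborage.

    For boundary d in 1..9 the ratio is mean density over deciles 1..d
    divided by mean density over deciles d+1..10 (the focal decile joins the
    upstream side, so every boundary is used exactly once); positive log2
    ratios mean more polymerase upstream. A boundary's focal decile harbors
    a RAP if a same-strand RAP overlaps it by >= 1 base. Genes with a zero
    denominator at a boundary are excluded from that boundary and counted in
    the ``excluded_zero_denominator`` DataFrame attribute.
    """
    rap_ivs = [r.interval if isinstance(r, RapPeak) else r for r in raps]
    rows = []
    n_zero = 0
    profiles, _ = decile_profiles(genes, track, trim)
    by_id = {g.feature_id: g for g in genes}
    for prof in profiles:
        gene = by_id[prof.gene_id]
        dens = prof.densities
        harbors = []
        for d in range(1, 11):
            seg_iv = _decile_genomic_interval(gene, trim, d)
            harbors.append(any(seg_iv.overlaps(riv) for riv in rap_ivs))
        for d in range(1, 10):
            up = dens[:d].mean()
            down = dens[d:].mean()
            if down == 0:
                n_zero += 1
                continue
            if up == 0:
                ratio = -np.inf
            else:
                ratio = float(np.log2(up / down))
            rows.append(
                {
                    "gene_id": prof.gene_id,
                    "boundary": d,
                    "log2_ratio": ratio,
                    "harbors_rap": harbors[d - 1],
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "boundary", "log2_ratio", "harbors_rap"])
    df.attrs["excluded_zero_denominator"] = n_zero
    return df


def decile_ks_comparison(df: pd.DataFrame, min_n: int = 5) -> dict:
    """Per-boundary KS comparison of RAP-harboring vs RAP-free log2 ratios.

    The up/down ratio distribution depends on the boundary index d (few vs
    many deciles on each side), so the two groups are compared within each
    boundary and combined with a Bonferroni correction over the boundaries
    tested. Returns per-boundary statistics plus the Bonferroni-corrected
    minimum p under ``"p_combined"``.
    """
    per_boundary = {}
    for d in sorted(df["boundary"].unique()):
        sub = df[df["boundary"] == d]
        a = sub.loc[sub["harbors_rap"], "log2_ratio"].to_numpy()
        b = sub.loc[~sub["harbors_rap"], "log2_ratio"].to_numpy()
        if len(a) < min_n or len(b) < min_n:
            continue
        ks = stats.ks_2samp(a, b, method="auto")
        per_boundary[int(d)] = {
            "n_rap": int(len(a)),
            "n_other": int(len(b)),
            "ks_stat": float(ks.statistic),
            "p": float(ks.pvalue),
        }
    if per_boundary:
        m = len(per_boundary)
        p_comb = min(1.0, min(v["p"] for v in per_boundary.values()) * m)
    else:
        p_comb = 1.0
    return {"boundaries": per_boundary, "p_combined": p_comb}


@dataclass
class UpDownCall:
    """Result of the exact up/down Poisson-rate comparison for one placement."""

    rap_id: str
    gene_id: str
    n_up: int
    length_up: int
    n_down: int
    length_down: int
    log2_ratio: float  # 0 when not significant, per the ratio-set-to-0 rule
    p: float
    call: str


def updown_exact_p(n_up: int, n_down: int, length_up: int, length_down: int) -> float:
    """Exact conditional two-Poisson-rate p: minimum-likelihood binomial tail
    of ``n_up`` out of the total at success probability L_up/(L_up+L_down)."""
    if n_up == 0 and n_down == 0:
        return 1.0
    p0 = length_up / (length_up + length_down)
    return float(stats.binomtest(n_up, n_up + n_down, p0).pvalue)


def _oriented_rap_bounds(gene: Feature, rap_iv: GenomicInterval) -> tuple[int, int]:
    """RAP start/end in transcription-oriented gene coordinates."""
    g = gene.interval
    if g.strand == MINUS:
        return g.end - rap_iv.end, g.end - rap_iv.start
    return rap_iv.start - g.start, rap_iv.end - g.start


def rap_updown_test(
    rap: RapPeak | GenomicInterval,
    gene: Feature,
    track: CoverageTrack,
    trim: int = 200,
    alpha: float = 0.01,
    rap_id: str = "",
) -> UpDownCall:
    """Exact conditional Poisson-rate test of upstream vs downstream density.

    Counts are track sums rounded half-to-even; the p-value is the
    minimum-likelihood two-sided binomial tail of ``n_up`` out of
    ``n_up + n_down`` at success probability ``L_up / (L_up + L_down)``.
    Calls use strict ``p < alpha``.
    """
    rap_iv = rap.interval if isinstance(rap, RapPeak) else rap
    g = gene.interval
    L = g.length
    rs, re = _oriented_rap_bounds(gene, rap_iv)
    lup = rs - trim
    ldown = (L - trim) - re
    if lup < 20 or ldown < 20:
        raise ValueError(
            f"RAP {rap_id or rap_iv} leaves up/down regions {lup}/{ldown} nt (< 20)"
        )
    sig = gene_signal(track, gene)
    n_up = round(float(sig[trim:rs].sum()))
    n_down = round(float(sig[re : L - trim].sum()))
    if n_up == 0 and n_down == 0:
        return UpDownCall(
            rap_id, gene.feature_id, 0, lup, 0, ldown, 0.0, 1.0, NOCHANGE
        )
    p = updown_exact_p(n_up, n_down, lup, ldown)
    du = n_up / lup
    dd = n_down / ldown
    if p < alpha and dd != du:
        call = DECREASE if dd < du else INCREASE
        if dd == 0:
            ratio = np.inf
        elif du == 0:
            ratio = -np.inf
        else:
            ratio = float(np.log2(du / dd))
    else:
        call = NOCHANGE
        ratio = 0.0
    return UpDownCall(rap_id, gene.feature_id, n_up, lup, n_down, ldown, ratio, p, call)


def _host_gene(rap_iv: GenomicInterval, genes: Sequence[Feature], trim: int) -> Feature | None:
    for g in genes:
        giv = g.interval
        if (
            giv.chrom == rap_iv.chrom
            and giv.strand == rap_iv.strand
            and giv.start + trim <= rap_iv.start
            and rap_iv.end <= giv.end - trim
        ):
            return g
    return None


def rap_updown_tests(
    raps: Sequence[RapPeak | GenomicInterval],
    genes: Sequence[Feature],
    track: CoverageTrack,
    trim: int = 200,
    alpha: float = 0.01,
) -> tuple[list[UpDownCall], list[tuple[str, str]]]:
    """Up/down calls for every RAP lying fully inside a same-strand trimmed
    gene body with >= 20 nt on each side; others are excluded with a reason."""
    calls, excluded = [], []
    for i, rap in enumerate(raps):
        rap_iv = rap.interval if isinstance(rap, RapPeak) else rap
        rid = getattr(rap, "name", "") or f"rap{i}"
        gene = _host_gene(rap_iv, genes, trim)
        if gene is None:
            excluded.append((rid, "not inside a trimmed same-strand gene body"))
            continue
        try:
            calls.append(rap_updown_test(rap, gene, track, trim, alpha, rap_id=rid))
        except ValueError as exc:
            excluded.append((rid, str(exc)))
    if excluded:
        log.info("rap_updown_tests: excluded %d RAPs", len(excluded))
    return calls, excluded


def randomized_background(
    calls: Sequence[UpDownCall],
    genes: Sequence[Feature],
    track: CoverageTrack,
    trim: int = 200,
    alpha: float = 0.01,
    n_per_rap: int = 100,
    seed: int = 0,
) -> list[UpDownCall]:
    """Background calls: each observed RAP re-placed on ``n_per_rap`` genes at
    the same position relative to the trimmed gene body.

    Eligible target genes have a trimmed body >= 200 nt and nonzero signal.
    Placements leaving an up or down region < 20 nt are re-drawn up to 10
    times, then skipped.
    """
    rng = rng_from_seed(seed, 17)
    by_id = {g.feature_id: g for g in genes}
    eligible = []
    for g in genes:
        if g.interval.length - 2 * trim < 200:
            continue
        if gene_signal(track, g)[trim : g.interval.length - trim].sum() <= 0:
            continue
        eligible.append(g)
    if not eligible:
        raise ValueError("no eligible background genes")
    background: list[UpDownCall] = []
    for call in calls:
        host = by_id[call.gene_id]
        body_len = host.interval.length - 2 * trim
        f1 = call.length_up / body_len  # = (rs - trim) / body_len
        f2 = (body_len - call.length_down) / body_len
        replace = len(eligible) < n_per_rap
        idx = rng.choice(len(eligible), size=n_per_rap, replace=replace)
        for slot, gi in enumerate(idx):
            placed = None
            tries = 0
            gidx = int(gi)
            while tries < 10:
                target = eligible[gidx]
                tb = target.interval.length - 2 * trim
                t1 = round(f1 * tb)
                t2 = round(f2 * tb)
                if t2 <= t1:
                    t2 = t1 + 1
                if t1 >= 20 and (tb - t2) >= 20 and t2 <= tb:
                    placed = (target, t1, t2)
                    break
                tries += 1
                gidx = int(rng.integers(0, len(eligible)))
            if placed is None:
                log.info("background placement for %s skipped", call.rap_id)
                continue
            target, t1, t2 = placed
            giv = target.interval
            if giv.strand == MINUS:
                iv = GenomicInterval(
                    giv.chrom, giv.end - trim - t2, giv.end - trim - t1, giv.strand
                )
            else:
                iv = GenomicInterval(
                    giv.chrom, giv.start + trim + t1, giv.start + trim + t2, giv.strand
                )
            background.append(
                rap_updown_test(
                    iv, target, track, trim, alpha, rap_id=f"{call.rap_id}_bg{slot}"
                )
            )
    return background


@dataclass
class BackgroundComparison:
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    chi2_p: float
    ks_stat: float
    ks_p: float
    merged: bool  # increase+decrease pooled because an expected count was < 1


def compare_to_background(
    observed_calls: Sequence[UpDownCall], background_calls: Sequence[UpDownCall]
) -> BackgroundComparison:
    """Chi-squared of observed category counts against background-derived
    expectations, plus two-sample KS on the log2-ratio distributions
    (nochange zeros included in both samples)."""
    if not observed_calls or not background_calls:
        raise ValueError("need non-empty observed and background call sets")
    n_obs = len(observed_calls)
    obs = {c: sum(1 for x in observed_calls if x.call == c) for c in CATEGORIES}
    n_bg = len(background_calls)
    prop = {c: sum(1 for x in background_calls if x.call == c) / n_bg for c in CATEGORIES}
    exp = {c: prop[c] * n_obs for c in CATEGORIES}
    merged = any(e < 1 for e in exp.values())
    if merged:
        log.warning("expected count < 1: pooling increase+decrease, df = 1")
        obs_v = [obs[INCREASE] + obs[DECREASE], obs[NOCHANGE]]
        exp_v = [exp[INCREASE] + exp[DECREASE], exp[NOCHANGE]]
        df = 1
    else:
        obs_v = [obs[c] for c in CATEGORIES]
        exp_v = [exp[c] for c in CATEGORIES]
        df = 2
    chi2 = 0.0
    for o, e in zip(obs_v, exp_v):
        if e > 0:
            chi2 += (o - e) ** 2 / e
        elif o > 0:
            chi2 = float("inf")
    chi2_p = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else 0.0
    ks = stats.ks_2samp(
        [x.log2_ratio for x in observed_calls],
        [x.log2_ratio for x in background_calls],
        method="asymp",
    )
    return BackgroundComparison(
        observed=obs,
        expected=exp,
        chi2=float(chi2),
        df=df,
        chi2_p=chi2_p,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        merged=merged,
    )
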