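"""Shared domain types, file formats, configuration and logging.

Coordinates are 0-based half-open throughout (BED convention); GFF3's 1-based
closed coordinates are converted at the file boundary. All randomized
operations take an explicit integer seed and are byte-reproducible.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."
STRANDS = (PLUS, MINUS)

#: Controlled feature-class vocabulary; unknown classes are kept verbatim
#: with a warning.
KNOWN_FEATURE_CLASSES = frozenset(
    {
        "ORF",
        "gene",
        "ncRNA",
        "rRNA",
        "tRNA",
        "snoRNA",
        "telomere",
        "telomeric_repeat",
        "X_element",
        "Y_prime",
        "LTR",
        "ARS",
    }
)

log = logging.getLogger("rapscan")


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


def rng_from_seed(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent generator from ``seed`` and an optional stream key.

    Uses :class:`numpy.random.SeedSequence` spawning so different keys give
    statistically independent streams while remaining fully reproducible.
    """
    if key:
        return np.random.default_rng(np.random.SeedSequence((seed, *key)))
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ChromSizes(dict):
    """Mapping of chromosome name to length in nucleotides."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self[name] = int(length)

    @property
    def total_length(self) -> int:
        return sum(self.values())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one base shared, on compatible strands."""
        if self.chrom != other.chrom:
            return False
        if UNSTRANDED not in (self.strand, other.strand) and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def validate(self, chrom_sizes: ChromSizes) -> None:
        if self.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > chrom_sizes[self.chrom]:
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {chrom_sizes[self.chrom]}"
            )


@dataclass(frozen=True)
class Feature:
    """An annotated genomic feature (gene, ncRNA, telomere tract, ...)."""

    interval: GenomicInterval
    feature_class: str
    feature_id: str

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class MatePair:
    """A mapped SELEX mate pair: chromosome plus the two mate 5'-end coordinates.

    ``chrom_b`` is ``None`` for concordant (same-chromosome) pairs and names
    the second chromosome for discordant pairs, which are retained by the
    reader and removed (and counted) by the filter stage.
    """

    chrom: str
    end5_a: int
    end5_b: int
    strand: str = UNSTRANDED
    chrom_b: str | None = None

    @property
    def is_cross_chromosome(self) -> bool:
        return self.chrom_b is not None and self.chrom_b != self.chrom

    @property
    def span(self) -> int:
        """Distance between the mate 5' ends."""
        return abs(self.end5_b - self.end5_a)

    @property
    def lo(self) -> int:
        return min(self.end5_a, self.end5_b)

    @property
    def hi(self) -> int:
        """Exclusive end of the covered fragment, ``max(5' ends) + 1``."""
        return max(self.end5_a, self.end5_b) + 1


class CoverageTrack:
    """Per-(chromosome, strand) dense non-negative signal, one value per base.

    ``signal_kind`` distinguishes integer fragment coverage from Pol II
    read-end counts, which may be fractional (multi-mapper weights).
    """

    def __init__(self, chrom_sizes: ChromSizes, signal_kind: str = "fragment_coverage"):
        if signal_kind not in ("fragment_coverage", "read_end_counts"):
            raise ValueError(f"unknown signal_kind {signal_kind!r}")
        self.chrom_sizes = chrom_sizes
        self.signal_kind = signal_kind
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def get(self, chrom: str, strand: str) -> np.ndarray:
        """Return the dense vector for (chrom, strand), creating zeros lazily."""
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.float64)
        return self._data[key]

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def total(self) -> float:
        return float(sum(v.sum() for v in self._data.values()))

    def validate(self) -> None:
        for (chrom, _), vec in self._data.items():
            if len(vec) != self.chrom_sizes[chrom]:
                raise ValueError(f"track length mismatch on {chrom}")
            if (vec < 0).any():
                raise ValueError(f"negative signal on {chrom}")


@dataclass(frozen=True)
class RapPeak:
    """A called RAP peak.

    ``interval.start`` is the position of maximal ascending smoothed
    derivative, ``interval.end - 1`` the position of maximal descending
    derivative; the derivative values at those positions are stored signed
    (ascend > 0, descend < 0).
    """

    interval: GenomicInterval
    max_ascend_value: float
    max_descend_value: float
    peak_coverage: float
    support_reads: int
    name: str = ""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults."""

    # peak caller
    min_region_coverage: int = 5
    kernel_window: int = 5
    kernel_sigma: float = 1.0
    min_peak_len: int = 20
    max_peak_len: int = 500
    min_pair_span: int = 20
    max_pair_span: int = 500
    stranded: bool = True
    # enrichment
    n_boot: int = 100_000
    seed: int = 0
    # occupancy
    trim: int = 200
    n_deciles: int = 10
    alpha: float = 0.01
    n_background_genes: int = 100
    # expression
    segment_bounds: tuple[float, ...] = (1.0, 30.0, 80.0)

    def __post_init__(self) -> None:
        for name in (
            "min_region_coverage",
            "kernel_window",
            "min_peak_len",
            "max_peak_len",
            "n_boot",
            "trim",
            "n_deciles",
            "n_background_genes",
        ):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_peak_len >= self.max_peak_len:
            raise ValueError("min_peak_len must be < max_peak_len")
        if self.kernel_window % 2 != 1:
            raise ValueError("kernel_window must be odd")
        self.segment_bounds = tuple(float(b) for b in self.segment_bounds)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Two-column TSV: chromosome name, length."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, length = parts[0], parts[1]
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = int(length)
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sizes:
            fh.write(f"{name}\t{sizes[name]}\n")


def _mate_5prime(start: int, end: int, strand: str) -> int:
    # Declared BEDPE dialect: the 5' end of a + mate is its start, of a - mate
    # its end - 1; the pair's transcribed strand is the strand1 column.
    if strand == MINUS:
        return end - 1
    return start


def read_bedpe(path: str | Path) -> list[MatePair]:
    """Read mapped SELEX mate pairs from BEDPE.

    Cross-chromosome records are retained but flagged so the filter stage can
    count them; no span filtering happens here.
    """
    pairs: list[MatePair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: expected >= 10 BEDPE columns")
            try:
                c1, s1, e1, c2, s2, e2 = (
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3],
                    int(parts[4]),
                    int(parts[5]),
                )
                st1, st2 = parts[8], parts[9]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE line") from exc
            pairs.append(
                MatePair(
                    chrom=c1,
                    end5_a=_mate_5prime(s1, e1, st1),
                    end5_b=_mate_5prime(s2, e2, st2),
                    strand=st1 if st1 in (PLUS, MINUS) else UNSTRANDED,
                    chrom_b=None if c1 == c2 else c2,
                )
            )
    return pairs


def write_bedpe(pairs: Sequence[MatePair], path: str | Path) -> None:
    """Write mate pairs as BEDPE; each mate is emitted as its 1-bp 5' base."""
    flip = {PLUS: MINUS, MINUS: PLUS, UNSTRANDED: UNSTRANDED}
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            c2 = p.chrom_b if p.chrom_b is not None else p.chrom
            st1 = p.strand
            st2 = flip[st1]
            a5, b5 = p.end5_a, p.end5_b
            # invert _mate_5prime: a 1-bp mate [x, x+1) has 5' end x on both strands
            fh.write(
                f"{p.chrom}\t{a5}\t{a5 + 1}\t{c2}\t{b5}\t{b5 + 1}\t"
                f"pair{i}\t.\t{st1}\t{st2}\n"
            )


def _parse_gff3(path: str | Path, chrom_sizes: ChromSizes) -> list[Feature]:
    features: list[Feature] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            fid = ""
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    fid = item[3:]
                    break
            if not fid:
                fid = f"{ftype}:{chrom}:{start_i}"
            # GFF3 1-based closed -> 0-based half-open
            iv = GenomicInterval(
                chrom, start_i - 1, end_i, strand if strand in (PLUS, MINUS) else UNSTRANDED
            )
            iv.validate(chrom_sizes)
            if fid in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen_ids.add(fid)
            if ftype not in KNOWN_FEATURE_CLASSES:
                log.warning("unknown feature class %r at %s:%d", ftype, path, lineno)
            features.append(Feature(iv, ftype, fid))
    return features


def _parse_bed_features(path: str | Path, chrom_sizes: ChromSizes) -> list[Feature]:
    features: list[Feature] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _, strand = parts[:6]
            # BED name convention "class:id"
            if ":" in name:
                fclass, fid = name.split(":", 1)
            else:
                fclass, fid = name, name
            iv = GenomicInterval(
                chrom, int(start), int(end), strand if strand in (PLUS, MINUS) else UNSTRANDED
            )
            iv.validate(chrom_sizes)
            if fid in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen_ids.add(fid)
            if fclass not in KNOWN_FEATURE_CLASSES:
                log.warning("unknown feature class %r at %s:%d", fclass, path, lineno)
            features.append(Feature(iv, fclass, fid))
    return features


def read_annotation(path: str | Path, chrom_sizes: ChromSizes) -> list[Feature]:
    """Read a GFF3 (.gff/.gff3) or BED6 annotation into Features."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return _parse_gff3(path, chrom_sizes)
    if p.endswith(".bed"):
        return _parse_bed_features(path, chrom_sizes)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff"):
        return _parse_gff3(path, chrom_sizes)
    return _parse_bed_features(path, chrom_sizes)


def write_annotation(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\trapscan\t{f.feature_class}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != UNSTRANDED else '.'}\t.\tID={f.feature_id}\n"
            )


_RAP_HEADER = "#chrom\tstart\tend\tname\tsupport_reads\tstrand\tmax_ascend\tmax_descend\tpeak_coverage"


def write_raps(peaks: Sequence[RapPeak], path: str | Path) -> None:
    """Write peaks as BED6 plus three statistic columns (full float precision)."""
    with open(path, "w") as fh:
        fh.write(_RAP_HEADER + "\n")
        for i, pk in enumerate(peaks):
            iv = pk.interval
            name = pk.name or f"RAP{i + 1:05d}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{pk.support_reads}\t"
                f"{iv.strand}\t{float(pk.max_ascend_value)!r}\t{float(pk.max_descend_value)!r}\t"
                f"{float(pk.peak_coverage)!r}\n"
            )


def read_raps(path: str | Path) -> list[RapPeak]:
    peaks: list[RapPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            chrom, start, end, name, score, strand = parts[:6]
            asc = float(parts[6]) if len(parts) > 6 else 0.0
            desc = float(parts[7]) if len(parts) > 7 else 0.0
            cov = float(parts[8]) if len(parts) > 8 else 0.0
            peaks.append(
                RapPeak(
                    GenomicInterval(
                        chrom,
                        int(start),
                        int(end),
                        strand if strand in (PLUS, MINUS) else UNSTRANDED,
                    ),
                    max_ascend_value=asc,
                    max_descend_value=desc,
                    peak_coverage=cov,
                    support_reads=int(score),
                    name=name,
                )
            )
    return peaks


def _read_one_bedgraph(path: str | Path, chrom_sizes: ChromSizes, track: CoverageTrack, strand: str) -> None:
    written: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            vec = track.get(chrom, strand)
            if end > len(vec) or start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval for {chrom}")
            mask = written.setdefault(chrom, np.zeros(len(vec), dtype=bool))
            if mask[start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph intervals")
            mask[start:end] = True
            vec[start:end] = value


def read_bedgraph(
    path_plus: str | Path,
    path_minus: str | Path | None,
    chrom_sizes: ChromSizes,
    signal_kind: str = "read_end_counts",
) -> CoverageTrack:
    """Read one bedGraph per strand into a dense CoverageTrack.

    Zero runs omitted on write are re-densified to 0. Pass ``path_minus=None``
    for an unstranded track (stored under strand '.').
    """
    track = CoverageTrack(chrom_sizes, signal_kind)
    if path_minus is None:
        _read_one_bedgraph(path_plus, chrom_sizes, track, UNSTRANDED)
    else:
        _read_one_bedgraph(path_plus, chrom_sizes, track, PLUS)
        _read_one_bedgraph(path_minus, chrom_sizes, track, MINUS)
    # touch every chromosome so downstream code sees full-length zero vectors
    for chrom in chrom_sizes:
        for strand in ((UNSTRANDED,) if path_minus is None else STRANDS):
            track.get(chrom, strand)
    return track


def _write_one_bedgraph(track: CoverageTrack, strand: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            vec = track.get(chrom, strand)
            # run-length encode, omitting zero runs
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def write_bedgraph(
    track: CoverageTrack, path_plus: str | Path, path_minus: str | Path | None = None
) -> None:
    if path_minus is None:
        _write_one_bedgraph(track, UNSTRANDED, path_plus)
    else:
        _write_one_bedgraph(track, PLUS, path_plus)
        _write_one_bedgraph(track, MINUS, path_minus)


def read_expression(path: str | Path) -> list[tuple[str, float]]:
    """Two-column TSV: gene_id, TPM. A 'gene_id' header line is skipped."""
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in ("gene_id", "gene"):
                continue
            try:
                tpm = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed TPM value") from exc
            if tpm < 0:
                raise ValueError(f"{path}:{lineno}: negative TPM")
            rows.append((parts[0], tpm))
    return rows


def write_expression(rows: Sequence[tuple[str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for gid, tpm in rows:
            fh.write(f"{gid}\t{float(tpm)!r}\n")
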