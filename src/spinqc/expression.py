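"""Expression-side quality assessment on per-transcript mapped-read counts:
coverage, length-count correlation, library-size correction, exclusive-
presence calls between two libraries, and saturation-curve assembly.

The differential call here is deliberately minimal. With one library per
condition and no replicates there is no dispersion to estimate, so no
count-model test is attempted: a transcript is called *exclusive* to one
library when the other library mapped exactly zero reads to it and the
(library-size-corrected) count in the first reaches a threshold (default
1000). This detects presence/absence between conditions, not quantitative
expression change.

Library-size correction is a single multiplicative factor,
``smaller_total / larger_total``, applied to the larger library's counts
so that neither library is advantaged by sequencing depth. Correction is
applied before thresholding; corrected counts stay real-valued, and a
zero raw count remains the (uncorrected) requirement on the silent side,
since scaling can neither create nor destroy zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import CountRecord


@dataclass
class LibraryPair:
    """Counts of two libraries over one shared transcript universe.

    ``n_reads_a`` / ``n_reads_b`` are the library totals used for mapping
    (the correction-factor denominators), not the sums of mapped counts.
    Transcript id sets are equalized by zero-filling on construction.
    """

    name_a: str
    name_b: str
    counts_a: dict[str, CountRecord]
    counts_b: dict[str, CountRecord]
    n_reads_a: int
    n_reads_b: int

    def __post_init__(self) -> None:
        if self.n_reads_a < 1 or self.n_reads_b < 1:
            raise ValueError("library totals must be >= 1")
        lengths: dict[str, int] = {}
        for rec in list(self.counts_a.values()) + list(self.counts_b.values()):
            lengths[rec.transcript_id] = rec.length
        for tid, length in lengths.items():
            if tid not in self.counts_a:
                self.counts_a[tid] = CountRecord(tid, length, 0)
            if tid not in self.counts_b:
                self.counts_b[tid] = CountRecord(tid, length, 0)

    @classmethod
    def from_records(
        cls,
        records_a: Iterable[CountRecord],
        records_b: Iterable[CountRecord],
        n_reads_a: Optional[int] = None,
        n_reads_b: Optional[int] = None,
        name_a: str = "a",
        name_b: str = "b",
    ) -> "LibraryPair":
        """Build a pair from record streams; totals default to summed mapped counts."""
        ca = {r.transcript_id: r for r in records_a}
        cb = {r.transcript_id: r for r in records_b}
        return cls(
            name_a=name_a,
            name_b=name_b,
            counts_a=ca,
            counts_b=cb,
            n_reads_a=n_reads_a
            if n_reads_a is not None
            else sum(r.mapped for r in ca.values()),
            n_reads_b=n_reads_b
            if n_reads_b is not None
            else sum(r.mapped for r in cb.values()),
        )


@dataclass
class DEConfig:
    """Exclusive-presence call parameters.

    ``min_reads``: corrected-count threshold on the expressed side
    (default 1000, compared with >=). ``zero_required``: when True (the
    default) the silent side must have exactly zero raw mapped reads; when
    False the silent side merely has to stay below ``min_reads``.
    """

    min_reads: int = 1000
    zero_required: bool = True

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def correction_factor(n_reads_a: int, n_reads_b: int) -> tuple[float, str]:
    """Library-size correction factor and which library it scales.

    Returns ``(factor, scaled)`` where ``factor = smaller / larger`` to six
    decimals and ``scaled`` is ``"a"`` or ``"b"`` — the *larger* library,
    whose per-transcript counts are multiplied by the factor.
    """
    if n_reads_a < 1 or n_reads_b < 1:
        raise ValueError("library totals must be >= 1")
    if n_reads_a >= n_reads_b:
        return round(n_reads_b / n_reads_a, 6), "a"
    return round(n_reads_a / n_reads_b, 6), "b"


def corrected_counts(pair: LibraryPair) -> tuple[dict[str, float], dict[str, float]]:
    """Per-transcript counts with the larger library scaled down.

    Corrected counts are kept as reals; no rounding before thresholding.
    """
    factor, scaled = correction_factor(pair.n_reads_a, pair.n_reads_b)
    fa = factor if scaled == "a" else 1.0
    fb = factor if scaled == "b" else 1.0
    a = {t: r.mapped * fa for t, r in pair.counts_a.items()}
    b = {t: r.mapped * fb for t, r in pair.counts_b.items()}
    return a, b


def coverage(record: CountRecord) -> float:
    """Mapped reads per base pair of the transcript."""
    return record.mapped / record.length


@dataclass
class CoverageSummary:
    """Coverage distribution over the full transcript set; percentages at 2 dp."""

    n: int
    mean_coverage: float
    pct_ge_1: float  # coverage >= 1 read/bp
    pct_1_to_10: float  # coverage in [1, 10)
    pct_gt_100: float  # coverage > 100 reads/bp
    pct_zero_reads: float
    pct_one_read: float
    pct_gt_10000_reads: float


def coverage_summary(records: Sequence[CountRecord]) -> CoverageSummary:
    if len(records) == 0:
        raise ValueError("empty record set")
    cov = np.array([coverage(r) for r in records])
    mapped = np.array([r.mapped for r in records])
    n = len(records)

    def pct(mask: np.ndarray) -> float:
        return round(100.0 * int(mask.sum()) / n, 2)

    return CoverageSummary(
        n=n,
        mean_coverage=float(cov.mean()),
        pct_ge_1=pct(cov >= 1),
        pct_1_to_10=pct((cov >= 1) & (cov < 10)),
        pct_gt_100=pct(cov > 100),
        pct_zero_reads=pct(mapped == 0),
        pct_one_read=pct(mapped == 1),
        pct_gt_10000_reads=pct(mapped > 10000),
    )


def length_count_correlation(
    records: Sequence[CountRecord],
) -> tuple[float, float]:
    """Pearson r and Spearman rho between transcript length and mapped count.

    Both coefficients are reported because at transcriptome scale the count
    distribution cannot be meaningfully tested for normality, so a rank
    statistic backs up the parametric one.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    lengths = np.array([r.length for r in records], dtype=float)
    counts = np.array([r.mapped for r in records], dtype=float)
    if lengths.std() == 0 or counts.std() == 0:
        raise ValueError("zero variance in lengths or counts")
    pearson_r = float(stats.pearsonr(lengths, counts).statistic)
    spearman_rho = float(stats.spearmanr(lengths, counts).statistic)
    return pearson_r, spearman_rho


def exclusive_transcripts(
    pair: LibraryPair, cfg: DEConfig = DEConfig()
) -> tuple[set[str], set[str]]:
    """Transcripts exclusively present in one library.

    Returns ``(exclusive_to_a, exclusive_to_b)``: zero raw reads on the
    other side (when ``zero_required``) and a corrected count of at least
    ``cfg.min_reads`` on the called side. The two sets are disjoint by
    construction and shrink monotonically as ``min_reads`` grows.
    """
    corr_a, corr_b = corrected_counts(pair)

    def silent(raw: int, corrected: float) -> bool:
        return raw == 0 if cfg.zero_required else corrected < cfg.min_reads

    excl_a = {
        t
        for t in pair.counts_a
        if corr_a[t] >= cfg.min_reads
        and silent(pair.counts_b[t].mapped, corr_b[t])
    }
    excl_b = {
        t
        for t in pair.counts_b
        if corr_b[t] >= cfg.min_reads
        and silent(pair.counts_a[t].mapped, corr_a[t])
    }
    return excl_a, excl_b


def unmapped_fraction(
    records: Sequence[CountRecord],
) -> tuple[int, int, float]:
    """Transcripts with zero mapped reads: count, percent (nearest int), percent (2 dp).

    Pass records whose ``mapped`` field pools all libraries to measure
    transcripts untouched by any read.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    count = sum(1 for r in records if r.mapped == 0)
    pct = 100.0 * count / len(records)
    return count, int(round(pct)), round(pct, 2)


def pooled_records(pair: LibraryPair) -> list[CountRecord]:
    """Sum both libraries' mapped counts per transcript."""
    return [
        CountRecord(
            t,
            pair.counts_a[t].length,
            pair.counts_a[t].mapped + pair.counts_b[t].mapped,
        )
        for t in sorted(pair.counts_a)
    ]


@dataclass
class SaturationPoint:
    """Per-subset analysis results backing one point of a saturation curve."""

    fraction: float
    n_transcripts: int
    n_unique_hits: int
    n_orthologs: Optional[int] = None
    nxx_values: Optional[tuple[int, int, int]] = None  # (n25, n50, n75)


@dataclass
class SaturationReport:
    points: list[SaturationPoint]
    plateau_index: Optional[int]

    @property
    def plateau_fraction(self) -> Optional[float]:
        if self.plateau_index is None:
            return None
        return self.points[self.plateau_index].fraction


def saturation_curve(
    points: Sequence[SaturationPoint], rel_tol: float = 0.01
) -> SaturationReport:
    """Assemble a gene-discovery saturation curve and flag its plateau.

    Fractions must be strictly increasing. The plateau is the first point
    whose unique-hit increment over the previous point falls below
    ``rel_tol`` relative to the previous value; with a single point no
    plateau is assessed.
    """
    pts = list(points)
    for prev, cur in zip(pts, pts[1:]):
        if cur.fraction <= prev.fraction:
            raise ValueError("fractions must be strictly increasing")
    plateau: Optional[int] = None
    for i in range(1, len(pts)):
        prev_u = pts[i - 1].n_unique_hits
        gain = pts[i].n_unique_hits - prev_u
        if prev_u > 0 and gain / prev_u < rel_tol:
            plateau = i
            break
    return SaturationReport(points=pts, plateau_index=plateau)
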