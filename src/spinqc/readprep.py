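"""Read preparation: 3' quality trimming, poly-A/T run removal, pair repair,
interleaving, and seeded random splitting/subsetting of paired reads.

The trimming rules mirror a common Illumina pre-assembly recipe: strip the
maximal 3' suffix in which every base falls below a Phred threshold
(default Q35), then strip terminal adenine or thymidine homopolymer runs
longer than a cutoff (default 10) from both ends. Internal low-quality
bases and internal homopolymers are never touched. Reads emptied by
trimming are dropped before pair repair, which separates mated pairs from
singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_formats import Read

ReadPair = tuple[Read, Read]


@dataclass
class TrimConfig:
    """Parameters of the trimming rules.

    min_q: Phred score; the maximal 3' suffix with every base below this
        is removed (default 35).
    max_homopolymer: terminal A or T runs strictly longer than this are
        removed; runs of exactly this length are retained (default 10).
    min_len_keep: reads shorter than this after trimming are dropped
        (default 1, i.e. only emptied reads are discarded).
    """

    min_q: int = 35
    max_homopolymer: int = 10
    min_len_keep: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.min_q <= 60:
            raise ValueError("min_q must be in [0, 60]")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")


def trim_quality_3prime(read: Read, cfg: TrimConfig) -> Read:
    """Remove the maximal 3' suffix in which every base is below ``cfg.min_q``.

    Internal bases below the threshold are kept: only the trailing
    all-below-threshold run goes. May return an empty read.
    """
    i = len(read.quals)
    while i > 0 and read.quals[i - 1] < cfg.min_q:
        i -= 1
    if i == len(read.quals):
        return read
    return replace(read, seq=read.seq[:i], quals=read.quals[:i])


def _leading_run(seq: str) -> int:
    if not seq or seq[0] not in "AT":
        return 0
    base = seq[0]
    i = 1
    while i < len(seq) and seq[i] == base:
        i += 1
    return i


def trim_polyA(read: Read, cfg: TrimConfig) -> Read:
    """Remove terminal A or T homopolymer runs longer than ``cfg.max_homopolymer``.

    Both ends are handled independently; sequence and qualities are cut
    together. Stripping is repeated until neither end carries a long run,
    so the operation is idempotent even when removing one run exposes
    another (e.g. an A-tail directly following a T-run).
    """
    seq, quals = read.seq, read.quals
    changed = True
    while changed:
        changed = False
        run = _leading_run(seq)
        if run > cfg.max_homopolymer:
            seq, quals = seq[run:], quals[run:]
            changed = True
        run = _leading_run(seq[::-1])
        if run > cfg.max_homopolymer:
            seq, quals = seq[:-run], quals[:-run]
            changed = True
    if seq == read.seq:
        return read
    return replace(read, seq=seq, quals=quals)


def trim_read(read: Read, cfg: TrimConfig) -> Read:
    """Full per-read trim: quality trim first, then poly-A/T removal."""
    return trim_polyA(trim_quality_3prime(read, cfg), cfg)


def trim_reads(reads: Iterable[Read], cfg: TrimConfig) -> Iterator[Read]:
    """Trim a stream, dropping reads shorter than ``cfg.min_len_keep``."""
    for read in reads:
        trimmed = trim_read(read, cfg)
        if len(trimmed) >= max(1, cfg.min_len_keep):
            yield trimmed


def repair_pairs(
    reads1: Iterable[Read], reads2: Iterable[Read]
) -> tuple[list[ReadPair], list[Read]]:
    """Separate mated pairs from singletons after trimming losses.

    Returns ``(pairs, singles)`` where ``pairs`` holds the id-stems present
    in both inputs (mate-1 file order) and ``singles`` the rest (mate-1
    leftovers first, then mate-2). Conserves reads:
    ``2*len(pairs) + len(singles) == len(in1) + len(in2)``.
    """
    d1: dict[str, Read] = {}
    for r in reads1:
        if r.id in d1:
            raise ValueError(f"duplicate read id {r.id!r} in mate-1 stream")
        d1[r.id] = r
    d2: dict[str, Read] = {}
    for r in reads2:
        if r.id in d2:
            raise ValueError(f"duplicate read id {r.id!r} in mate-2 stream")
        d2[r.id] = r
    pairs = [(d1[stem], d2[stem]) for stem in d1 if stem in d2]
    singles = [r for stem, r in d1.items() if stem not in d2]
    singles += [r for stem, r in d2.items() if stem not in d1]
    return pairs, singles


def interleave(pairs: Iterable[ReadPair]) -> Iterator[Read]:
    """Flatten pairs into a mate1-then-mate2 interleaved stream."""
    for r1, r2 in pairs:
        yield r1
        yield r2


def random_split(
    pairs: Sequence[ReadPair], k: int, seed: int
) -> list[list[ReadPair]]:
    """Assign every pair to exactly one of ``k`` parts uniformly at random.

    Pairs are never separated; the same seed yields the same assignment.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = list(pairs)
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, k, size=len(pairs))
    parts: list[list[ReadPair]] = [[] for _ in range(k)]
    for pair, part in zip(pairs, assignment):
        parts[part].append(pair)
    return parts


def random_subset(
    pairs: Sequence[ReadPair], fraction: float, seed: int
) -> list[ReadPair]:
    """Keep exactly ``round(fraction * n)`` pairs, chosen without replacement.

    Selection ranks pairs by a single seeded permutation, so subsets built
    from the same seed are nested: ``subset(0.1) <= subset(0.2)``. This
    makes saturation curves monotone by construction. Output preserves
    input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pairs = list(pairs)
    n = len(pairs)
    n_keep = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    rank = rng.permutation(n)
    keep = np.flatnonzero(rank < n_keep)
    return [pairs[i] for i in keep]
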