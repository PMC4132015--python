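"""Assembly-level statistics: NXX contig lengths, length distributions,
pooled GC content, and a longest-ORF coding-potential screen.

NXX follows the length-weighted convention used by assembly tools: sort
contigs by length descending and report the first length at which the
cumulative base count reaches X% of the total assembly size. (An
alternative count-based quantile reading exists in the literature; this
package implements only the length-weighted statistic and documents the
distinction in the methods note.)

The ORF model is deliberately simple: a maximal stop-free codon run
(stop-to-stop, start codon not required) in any of the six frames,
reported when it reaches a minimum residue count. It is a coding-potential
screen, not a gene predictor: no hexamer or codon-usage scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import Transcript, revcomp

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class OrfCall:
    """One stop-free codon run.

    ``start``/``end`` are 0-based half-open coordinates on the transcript's
    forward strand regardless of frame sign; ``frame`` is +1..+3 on the
    forward strand and -1..-3 on the reverse complement; ``end - start`` is
    always divisible by 3.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    aa_len: int
    is_primary: bool = False


@dataclass
class AssemblyStats:
    n_transcripts: int
    total_bp: int
    n25: int
    n50: int
    n75: int
    gc_all: float
    #: (bin_start, bin_end_exclusive_or_None, count); last bin open-ended
    length_histogram: list[tuple[int, Optional[int], int]]


def nxx(lengths: Sequence[int], x: float) -> int:
    """Length-weighted NXX of a set of contig lengths.

    Sort descending; return the first length at which the cumulative sum
    reaches at least ``x`` percent of total bases. Monotone non-increasing
    in ``x`` (N25 >= N50 >= N75).
    """
    if len(lengths) == 0:
        raise ValueError("nxx of an empty length list is undefined")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    cum = np.cumsum(arr)
    threshold = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, threshold, side="left"))
    return int(arr[idx])


def gc_content(seqs: Iterable[str]) -> float:
    """Pooled GC fraction: (G+C)/(A+C+G+T) over all sequences together.

    Ambiguity codes (N etc.) are excluded from numerator and denominator.
    Pooling, rather than averaging per-sequence GC, matches a single
    assembly-wide figure and is invariant to how the pool is partitioned.
    """
    gc = 0
    at = 0
    for seq in seqs:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in input")
    return gc / (gc + at)


def _frame_orfs(seq: str, offset: int, min_aa: int) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs in one frame of ``seq``.

    Returns (start, end) 0-based half-open coordinates on ``seq`` with
    end - start a multiple of 3 and (end - start) / 3 >= min_aa.
    """
    runs: list[tuple[int, int]] = []
    run_start = offset
    i = offset
    last_full = offset + 3 * ((len(seq) - offset) // 3)
    while i + 3 <= len(seq):
        if seq[i : i + 3] in _STOPS:
            if (i - run_start) // 3 >= min_aa:
                runs.append((run_start, i))
            run_start = i + 3
        i += 3
    if (last_full - run_start) // 3 >= min_aa:
        runs.append((run_start, last_full))
    return runs


def longest_orfs(transcript: Transcript, min_aa: int = 100) -> list[OrfCall]:
    """Six-frame scan for stop-free codon runs of at least ``min_aa`` residues.

    The longest run per transcript is flagged primary; ties break in favor
    of the forward strand, then the lowest forward-strand start.
    """
    seq = transcript.seq.upper()
    n = len(seq)
    calls: list[OrfCall] = []
    rc = revcomp(seq)
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            for start, end in _frame_orfs(s, offset, min_aa):
                if strand == 1:
                    fwd_start, fwd_end = start, end
                else:
                    fwd_start, fwd_end = n - end, n - start
                calls.append(
                    OrfCall(
                        transcript_id=transcript.id,
                        frame=strand * (offset + 1),
                        start=fwd_start,
                        end=fwd_end,
                        aa_len=(end - start) // 3,
                    )
                )
    if calls:
        calls.sort(key=lambda c: (-c.aa_len, 0 if c.frame > 0 else 1, c.start))
        calls[0].is_primary = True
    return calls


def length_fraction(
    lengths: Sequence[int], cutoff_bp: int, decimals: int = 1
) -> tuple[int, float]:
    """Count and rounded percentage of lengths strictly below ``cutoff_bp``."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    arr = np.asarray(lengths)
    count = int((arr < cutoff_bp).sum())
    return count, round(100.0 * count / len(arr), decimals)


def length_histogram(
    lengths: Sequence[int], bin_width: int = 100, bin_max: int = 2000
) -> list[tuple[int, Optional[int], int]]:
    """Fixed-width bins up to ``bin_max``, then a single open-ended bin."""
    arr = np.asarray(lengths)
    bins: list[tuple[int, Optional[int], int]] = []
    for lo in range(0, bin_max, bin_width):
        hi = lo + bin_width
        bins.append((lo, hi, int(((arr >= lo) & (arr < hi)).sum())))
    bins.append((bin_max, None, int((arr >= bin_max).sum())))
    return bins


def assembly_report(
    transcripts: Sequence[Transcript],
    bin_width: int = 100,
    bin_max: int = 2000,
) -> AssemblyStats:
    """Compute the full statistics block for one assembly."""
    if not transcripts:
        raise ValueError("empty assembly")
    lengths = [len(t.seq) for t in transcripts]
    return AssemblyStats(
        n_transcripts=len(transcripts),
        total_bp=int(sum(lengths)),
        n25=nxx(lengths, 25),
        n50=nxx(lengths, 50),
        n75=nxx(lengths, 75),
        gc_all=gc_content(t.seq for t in transcripts),
        length_histogram=length_histogram(lengths, bin_width, bin_max),
    )
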