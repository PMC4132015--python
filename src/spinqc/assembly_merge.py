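"""Stepwise-assembly bookkeeping: rescue filtering of assembler-unused
fragments, merging of sequence sets, and locus/isoform accounting for
Oases-style transcript identifiers (``Locus_i_Transcript_j/k_Confidence_c``).

A "locus" here is the assembler's cluster of presumed isoforms of one
gene. Transcripts whose ids do not follow the locus grammar each form a
singleton locus, so locus summaries always partition the transcript set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .io_formats import Transcript


@dataclass
class LocusSummary:
    locus_id: str
    length_list: list[int]

    @property
    def n_transcripts(self) -> int:
        return len(self.length_list)


@dataclass
class LocusAggregate:
    """Assembly-wide locus statistics."""

    n_loci: int
    n_transcripts: int
    mean_transcripts_per_locus: float
    #: number of loci with at least ``n`` transcripts, keyed by ``n``
    n_loci_with_at_least: dict[int, int]


def length_filter(
    seqs: Iterable[tuple[str, str]], min_exclusive: int = 110
) -> Iterator[tuple[str, str]]:
    """Keep sequences strictly longer than ``min_exclusive`` bp.

    This is the rescue rule for assembler-unused fragments: a 110 bp
    sequence is excluded, a 111 bp sequence kept.
    """
    for name, seq in seqs:
        if len(seq) > min_exclusive:
            yield name, seq


def merge_assemblies(
    primary: Sequence[Transcript],
    rescued: Sequence[Transcript],
    prefix: str = "rescue_",
) -> list[Transcript]:
    """Union of a primary assembly and a rescued fragment set.

    Id collisions are resolved by prefixing the rescued id, so the output
    always holds ``len(primary) + len(rescued)`` transcripts and the total
    base-pair count is conserved.
    """
    primary_ids = {t.id for t in primary}
    merged = list(primary)
    for t in rescued:
        if t.id in primary_ids:
            new_id = prefix + t.id
            if new_id in primary_ids:
                raise ValueError(f"cannot disambiguate rescued id {t.id!r}")
            t = Transcript(
                id=new_id,
                seq=t.seq,
                locus_id=t.locus_id,
                isoform_index=t.isoform_index,
                isoform_total=t.isoform_total,
            )
        merged.append(t)
    return merged


_LOCUS_RE = re.compile(
    r"^Locus_(\d+)_Transcript_(\d+)/(\d+)_Confidence_\d+(?:\.\d+)?"
)


def parse_locus_id(name: str) -> Optional[tuple[int, int, int]]:
    """Decompose an Oases-style id into ``(locus, isoform_index, isoform_total)``.

    Ids not matching the ``Locus_<i>_Transcript_<j>/<k>_Confidence_<c>``
    grammar return ``None``; trailing fields after the confidence value are
    ignored.
    """
    m = _LOCUS_RE.match(name)
    if m is None:
        return None
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def locus_complexity(
    transcripts: Sequence[Transcript],
    thresholds: Sequence[int] = (10, 100),
) -> tuple[list[LocusSummary], LocusAggregate]:
    """Group transcripts by locus and summarize cluster complexity.

    Transcripts carrying an explicit ``locus_id`` use it; otherwise the id
    is parsed with :func:`parse_locus_id`; unparseable ids each become a
    singleton locus. The mean is computed over all loci, the largest
    included.
    """
    groups: dict[str, list[int]] = {}
    for t in transcripts:
        if t.locus_id is not None:
            key = t.locus_id
        else:
            parsed = parse_locus_id(t.id)
            key = str(parsed[0]) if parsed is not None else t.id
        groups.setdefault(key, []).append(len(t.seq))
    summaries = [LocusSummary(k, v) for k, v in groups.items()]
    n_total = sum(s.n_transcripts for s in summaries)
    agg = LocusAggregate(
        n_loci=len(summaries),
        n_transcripts=n_total,
        mean_transcripts_per_locus=(n_total / len(summaries)) if summaries else 0.0,
        n_loci_with_at_least={
            n: sum(1 for s in summaries if s.n_transcripts >= n)
            for n in thresholds
        },
    )
    return summaries, agg


def locus_length_profile(
    summary: LocusSummary, cutoff: int = 500
) -> tuple[int, float]:
    """Count and percentage (1 decimal) of member transcripts shorter than ``cutoff``."""
    n_below = sum(1 for length in summary.length_list if length < cutoff)
    if not summary.length_list:
        return 0, 0.0
    return n_below, round(100.0 * n_below / len(summary.length_list), 1)
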