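"""Reciprocal-best-hit orthology and annotation summaries.

The operational definitions, standard for de novo transcriptome
annotation against a well-curated reference proteome:

* a transcript ``t`` whose best forward hit is reference gene ``g`` is an
  **ortholog** of ``g`` iff ``g``'s best reverse hit is ``t`` (reciprocal
  best hit, RBH);
* ``t`` is a **paralog** of ``g`` when the forward best hit exists but
  reciprocity fails — either ``g``'s best reverse hit is a different
  transcript, or ``g`` has no reverse hit at all;
* transcripts with no forward hit passing the e-value cutoff get no call.

The **ortholog hit ratio** (OHR) of a transcript is the fraction of its
best-hit reference protein covered by the single best HSP: subject-residue
span divided by protein length. An OHR of 1 marks a putatively full-length
transcript. HSPs are never merged — the ratio measures one contiguous
homologous block.

Because 12-column BLAST output carries neither subject lengths nor
taxonomy, both come from a reference sidecar (:class:`ReferenceDB`,
a TSV of accession / length / taxon, or the reference FASTA itself).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import BlastHit, PathLike, read_fasta


@dataclass(frozen=True)
class OrthologyCall:
    transcript_id: str
    status: str  # "ortholog" | "paralog" | "none"
    reference_gene: Optional[str] = None
    forward_evalue: Optional[float] = None
    ohr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("ortholog", "paralog", "none"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "none" and self.reference_gene is not None:
            raise ValueError("status 'none' forbids a reference gene")


@dataclass
class ReferenceDB:
    """Protein lengths and taxon labels for the reference gene set."""

    lengths: dict[str, int]
    taxa: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"protein length of {gene!r} must be >= 1")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "ReferenceDB":
        """Load an ``accession <TAB> length <TAB> taxon`` sidecar table."""
        lengths: dict[str, int] = {}
        taxa: dict[str, str] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                lengths[row[0]] = int(row[1])
                if len(row) > 2:
                    taxa[row[0]] = row[2]
        return cls(lengths=lengths, taxa=taxa)

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            for gene, length in self.lengths.items():
                taxon = self.taxa.get(gene, "")
                fh.write(f"{gene}\t{length}\t{taxon}\n")

    @classmethod
    def from_fasta(cls, path: PathLike, taxon: str = "") -> "ReferenceDB":
        lengths = {name: len(seq) for name, seq in read_fasta(path)}
        taxa = {name: taxon for name in lengths} if taxon else {}
        return cls(lengths=lengths, taxa=taxa)


@dataclass(frozen=True)
class PathwayComponent:
    name: str
    query_gene: str
    previously_known: bool = False


#: pathway name -> ordered list of components
PathwayTable = dict[str, list[PathwayComponent]]


def best_hits(
    hits: Iterable[BlastHit], evalue_cutoff: float = 1e-10
) -> dict[str, BlastHit]:
    """Single best hit per query among hits passing the e-value cutoff.

    Ranking is (higher bitscore, then lower e-value, then lexicographically
    smallest subject id) — fully deterministic across runs and platforms.
    """
    best: dict[str, BlastHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        cur = best.get(hit.qseqid)
        if cur is None or (-hit.bitscore, hit.evalue, hit.sseqid) < (
            -cur.bitscore,
            cur.evalue,
            cur.sseqid,
        ):
            best[hit.qseqid] = hit
    return best


def rbh_classify(
    fwd: Mapping[str, BlastHit],
    rev: Mapping[str, BlastHit],
    transcript_ids: Optional[Iterable[str]] = None,
) -> list[OrthologyCall]:
    """Classify transcripts as ortholog / paralog by reciprocal best hits.

    ``fwd`` maps transcript -> best hit in the reference proteome;
    ``rev`` maps reference gene -> best hit in the transcriptome. A gene
    absent from ``rev`` counts as a reciprocity failure, so its forward
    hits are paralogs rather than no-calls. When ``transcript_ids`` is
    given, transcripts without a forward hit are reported with status
    ``none``.
    """
    calls: list[OrthologyCall] = []
    for t in sorted(fwd):
        hit = fwd[t]
        g = hit.sseqid
        rev_hit = rev.get(g)
        status = (
            "ortholog" if rev_hit is not None and rev_hit.sseqid == t else "paralog"
        )
        calls.append(
            OrthologyCall(
                transcript_id=t,
                status=status,
                reference_gene=g,
                forward_evalue=hit.evalue,
            )
        )
    if transcript_ids is not None:
        for t in transcript_ids:
            if t not in fwd:
                calls.append(OrthologyCall(transcript_id=t, status="none"))
    return calls


@dataclass
class OrthologCounts:
    """Gene-level and call-level ortholog tallies.

    Whether an "orthologs incl. paralogs" figure counts reference genes or
    transcript-level calls is a genuinely ambiguous convention, so both
    tallies are carried.
    """

    genes_with_calls: int  # distinct genes hit by >=1 ortholog-or-paralog call
    genes_with_orthologs: int  # distinct genes with a strict RBH
    calls_total: int  # ortholog + paralog calls
    calls_ortholog: int


def ortholog_counts(calls: Sequence[OrthologyCall]) -> OrthologCounts:
    genes_any = {c.reference_gene for c in calls if c.status != "none"}
    genes_orth = {c.reference_gene for c in calls if c.status == "ortholog"}
    return OrthologCounts(
        genes_with_calls=len(genes_any),
        genes_with_orthologs=len(genes_orth),
        calls_total=sum(1 for c in calls if c.status != "none"),
        calls_ortholog=sum(1 for c in calls if c.status == "ortholog"),
    )


@dataclass
class UniqueHitStats:
    n_unique_subjects: int
    mean_queries_per_subject: float
    max_queries_per_subject: int
    min_queries_per_subject: int


def unique_hit_stats(fwd_best: Mapping[str, BlastHit]) -> UniqueHitStats:
    """Distinct best-hit subjects and the queries-per-subject distribution."""
    per_subject: dict[str, int] = {}
    for hit in fwd_best.values():
        per_subject[hit.sseqid] = per_subject.get(hit.sseqid, 0) + 1
    if not per_subject:
        return UniqueHitStats(0, 0.0, 0, 0)
    counts = list(per_subject.values())
    return UniqueHitStats(
        n_unique_subjects=len(per_subject),
        mean_queries_per_subject=sum(counts) / len(counts),
        max_queries_per_subject=max(counts),
        min_queries_per_subject=min(counts),
    )


def ohr(best_hit: BlastHit, db: ReferenceDB) -> float:
    """Ortholog hit ratio of one best hit: subject span / protein length.

    Uses the single best HSP only; clamped into (0, 1]. Invariant to the
    query-side coordinates and to subject strand (a reversed interval is
    normalized).
    """
    length = db.lengths.get(best_hit.sseqid)
    if length is None:
        raise KeyError(
            f"subject {best_hit.sseqid!r} missing from the reference sidecar"
        )
    return min(1.0, best_hit.subject_span() / length)


@dataclass
class OhrSummary:
    frac_ge_50: float
    frac_ge_80: float
    #: (bin_lo, bin_hi, count); bins [0,0.1) ... [0.9,1.0] (last inclusive)
    histogram: list[tuple[float, float, int]]
    n: int


def ohr_summary(ohrs: Sequence[float]) -> OhrSummary:
    """Proportions of transcripts at OHR >= 0.5 and >= 0.8, plus a 0.1-bin histogram."""
    if len(ohrs) == 0:
        raise ValueError("empty OHR list")
    n = len(ohrs)
    hist: list[tuple[float, float, int]] = []
    for i in range(10):
        lo, hi = i / 10, (i + 1) / 10
        if i < 9:
            count = sum(1 for v in ohrs if lo <= v < hi)
        else:
            count = sum(1 for v in ohrs if lo <= v <= hi)
        hist.append((lo, hi, count))
    return OhrSummary(
        frac_ge_50=sum(1 for v in ohrs if v >= 0.5) / n,
        frac_ge_80=sum(1 for v in ohrs if v >= 0.8) / n,
        histogram=hist,
        n=n,
    )


def species_distribution(
    fwd_best: Mapping[str, BlastHit], db: ReferenceDB
) -> dict[str, float]:
    """Proportion of best hits per taxon label; proportions sum to 1."""
    counts: dict[str, int] = {}
    total = 0
    for hit in fwd_best.values():
        taxon = db.taxa.get(hit.sseqid)
        if taxon is None:
            raise KeyError(f"subject {hit.sseqid!r} has no taxon label")
        counts[taxon] = counts.get(taxon, 0) + 1
        total += 1
    return {taxon: c / total for taxon, c in counts.items()}


def read_pathway_table(path: PathLike) -> PathwayTable:
    """Load a pathway component table.

    TSV columns: pathway, component, query_gene, previously_known (0/1).
    """
    table: PathwayTable = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            pathway, component, gene = row[0], row[1], row[2]
            known = len(row) > 3 and row[3] in ("1", "true", "True", "yes")
            table.setdefault(pathway, []).append(
                PathwayComponent(component, gene, known)
            )
    for pathway, comps in table.items():
        names = [c.name for c in comps]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate component names in pathway {pathway!r}")
    return table


def pathway_presence(
    table: PathwayTable, present_genes: Iterable[str]
) -> pd.DataFrame:
    """Per-pathway presence summary plus an overall row.

    A component is present when its query gene is in ``present_genes``
    (typically the reference genes with an ortholog-or-paralog call).
    Percentages are rounded to 2 decimals; the previously-known percentage
    is taken over the *present* components.
    """
    present = set(present_genes)
    rows = []
    for pathway, comps in table.items():
        n = len(comps)
        n_present = sum(1 for c in comps if c.query_gene in present)
        n_known = sum(
            1 for c in comps if c.query_gene in present and c.previously_known
        )
        rows.append((pathway, n, n_present, n_known))
    total = sum(r[1] for r in rows)
    total_present = sum(r[2] for r in rows)
    total_known = sum(r[3] for r in rows)
    rows.append(("overall", total, total_present, total_known))
    df = pd.DataFrame(
        rows, columns=["pathway", "n_components", "n_present", "n_previously_known"]
    )
    df["pct_present"] = (100.0 * df.n_present / df.n_components).round(2)
    df["pct_previously_known_of_present"] = [
        round(100.0 * k / p, 2) if p else 0.0
        for k, p in zip(df.n_previously_known, df.n_present)
    ]
    return df[
        [
            "pathway",
            "n_components",
            "n_present",
            "pct_present",
            "n_previously_known",
            "pct_previously_known_of_present",
        ]
    ]


def prediction_gain(n_new: int, n_old: int, mode: str = "increase") -> float:
    """Relative gain of a new annotation count over an old one, in percent.

    ``increase`` mode reports (n_new/n_old - 1) * 100 to 2 decimals;
    ``ratio`` mode reports (n_new/n_old) * 100 to the nearest integer.
    """
    if n_old < 1:
        raise ValueError("n_old must be >= 1")
    if mode == "increase":
        return round((n_new / n_old - 1.0) * 100.0, 2)
    if mode == "ratio":
        return float(round(n_new / n_old * 100.0))
    raise ValueError(f"unknown mode {mode!r}")
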