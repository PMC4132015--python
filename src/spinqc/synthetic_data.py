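"""Seeded generators for every input the pipeline consumes, with recorded
ground truth, so all stages are testable end to end without external data.

What is emulated
----------------
* a toy reference proteome with taxon labels (stand-in for a curated
  insect/chelicerate gene set);
* a multi-isoform transcriptome with Oases-style locus ids: each core
  locus carries one full-length transcript back-translated from a
  reference protein (the planted ortholog) plus truncated isoforms, and
  additional loci carry diverged copies (planted paralogs);
* 101 bp paired-end reads with Illumina-like 3'-degrading qualities and
  poly-A contamination, so the trimming rules have real work to do;
* 12-column BLAST tables in both search directions, with decoy hits at
  strictly lower bitscore and subject spans drawn to realize planted
  ortholog-hit-ratio values;
* two idxstats-style count libraries with planted stage-exclusive
  transcripts and negative-binomial count noise.

Every generator is a pure function of its arguments and seed: identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .io_formats import (
    BlastHit,
    CountRecord,
    PathLike,
    Read,
    Transcript,
    revcomp,
    write_blast_tab,
    write_counts_tsv,
    write_fasta,
    write_fastq,
)
from .orthology import ReferenceDB

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

# one codon per amino acid (arbitrary but fixed) keeps back-translation
# deterministic given the rng stream; a random synonymous choice per
# residue is drawn on top of this table
_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

DEFAULT_TAXA = ("Chelicerata", "Diptera", "Hymenoptera", "Mammalia")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset.

    ``orthology_map`` is a bijection on its domain (one transcript per
    reference gene); ``paralogs`` maps every other coding transcript to
    the gene it diverged or truncated from. ``orf_map`` stores planted ORF
    coordinates as ``(frame, start, end, aa_len)`` 0-based half-open on
    the forward strand. ``ohr_map`` holds the realized ortholog hit
    ratios of the simulated forward best hits.
    """

    orthology_map: dict[str, str] = field(default_factory=dict)
    paralogs: dict[str, str] = field(default_factory=dict)
    locus_map: dict[str, str] = field(default_factory=dict)
    orf_map: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    ohr_map: dict[str, float] = field(default_factory=dict)
    exclusive_a: list[str] = field(default_factory=list)
    exclusive_b: list[str] = field(default_factory=list)
    read_provenance: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: PathLike) -> None:
        data = {
            "orthology_map": self.orthology_map,
            "paralogs": self.paralogs,
            "locus_map": self.locus_map,
            "orf_map": {k: list(v) for k, v in self.orf_map.items()},
            "ohr_map": self.ohr_map,
            "exclusive_a": self.exclusive_a,
            "exclusive_b": self.exclusive_b,
            "read_provenance": self.read_provenance,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: PathLike) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        gt = cls(**{k: v for k, v in data.items() if k != "orf_map"})
        gt.orf_map = {k: tuple(v) for k, v in data["orf_map"].items()}
        return gt


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NT), size=n))


def _backtranslate(aa_seq: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in aa_seq
    )


# ---------------------------------------------------------------------------
# reference proteome
# ---------------------------------------------------------------------------


def make_reference_proteome(
    n_genes: int,
    length_range: tuple[int, int] = (100, 300),
    seed: int = 0,
    taxa: Sequence[str] = DEFAULT_TAXA,
) -> tuple[list[tuple[str, str]], ReferenceDB]:
    """Random protein sequences plus a length/taxon sidecar.

    Taxon labels are drawn uniformly from ``taxa`` so that the species
    distribution of best hits is exercised.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    proteins: list[tuple[str, str]] = []
    lengths: dict[str, int] = {}
    taxa_map: dict[str, str] = {}
    for i in range(n_genes):
        gene = f"g{i + 1:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(_AA), size=length))
        proteins.append((gene, seq))
        lengths[gene] = length
        taxa_map[gene] = taxa[int(rng.integers(0, len(taxa)))]
    return proteins, ReferenceDB(lengths=lengths, taxa=taxa_map)


# ---------------------------------------------------------------------------
# transcriptome with planted loci / orthologs / paralogs / ORFs
# ---------------------------------------------------------------------------


def make_transcriptome(
    proteins: Sequence[tuple[str, str]],
    n_loci: Optional[int] = None,
    isoforms_per_locus: int = 2,
    utr_range: tuple[int, int] = (30, 120),
    paralog_divergence: float = 0.15,
    seed: int = 0,
) -> tuple[list[Transcript], GroundTruth]:
    """Build a multi-isoform transcriptome with known coding structure.

    The first ``len(proteins)`` loci are *core* loci: their first isoform
    carries the full back-translated protein (the planted ortholog, a
    one-to-one map gene -> transcript) and further isoforms carry
    truncated copies. Loci beyond the proteome size carry diverged copies
    of a cycled source gene; all their isoforms, and all truncated core
    isoforms, are planted paralogs. Every coding region sits between
    in-frame stop codons, so its coordinates are recovered exactly by a
    six-frame stop-to-stop ORF scan.
    """
    if n_loci is None:
        n_loci = len(proteins)
    if isoforms_per_locus < 1:
        raise ValueError("isoforms_per_locus must be >= 1")
    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    gt = GroundTruth()
    n_genes = len(proteins)
    for locus in range(1, n_loci + 1):
        gene_id, protein = proteins[(locus - 1) % n_genes]
        core = locus <= n_genes
        if not core and paralog_divergence > 0:
            protein = _mutate_protein(protein, paralog_divergence, rng)
        k = isoforms_per_locus
        for iso in range(1, k + 1):
            aa = protein
            if iso > 1 or not core:
                if iso > 1:  # truncated isoform
                    frac = rng.uniform(0.5, 0.9)
                    aa = protein[: max(30, int(len(protein) * frac))]
            tid = f"Locus_{locus}_Transcript_{iso}/{k}_Confidence_1.000"
            utr5 = _random_nt(rng, int(rng.integers(*utr_range)))
            utr3 = _random_nt(rng, int(rng.integers(*utr_range)))
            cds = _backtranslate(aa, rng)
            stop = _STOPS[int(rng.integers(0, 3))]
            seq = utr5 + "TAA" + cds + stop + utr3
            start = len(utr5) + 3
            end = start + 3 * len(aa)
            transcripts.append(
                Transcript(
                    id=tid,
                    seq=seq,
                    locus_id=str(locus),
                    isoform_index=iso,
                    isoform_total=k,
                )
            )
            gt.locus_map[tid] = str(locus)
            gt.orf_map[tid] = (start % 3 + 1, start, end, len(aa))
            if core and iso == 1:
                gt.orthology_map[tid] = gene_id
            else:
                gt.paralogs[tid] = gene_id
    return transcripts, gt


def _mutate_protein(
    protein: str, divergence: float, rng: np.random.Generator
) -> str:
    out = []
    for aa in protein:
        if rng.random() < divergence:
            choices = _AA.replace(aa, "")
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------


def simulate_reads(
    transcripts: Sequence[Transcript],
    n_pairs: int,
    read_len: int = 101,
    insert: int = 250,
    polya_rate: float = 0.1,
    decay_rate: float = 0.3,
    decay_floor: int = 20,
    decay_len: int = 15,
    error_rate: float = 0.0,
    seed: int = 0,
    weights: Optional[Mapping[str, float]] = None,
) -> tuple[list[Read], list[Read], list[str]]:
    """Draw paired reads from the transcript pool.

    Pairs are sampled proportionally to ``weights`` (uniform over eligible
    transcripts when omitted); transcripts shorter than the insert size
    are skipped with a warning. A ``decay_rate`` fraction of reads gets a
    linear 3' quality decline from Q40 down to ``decay_floor`` over the
    last ``decay_len`` bases, and a ``polya_rate`` fraction gets its 3'
    end replaced by an 11-15 base adenine run — both chosen so the
    standard trimming rules (Q35 suffix, >10-base homopolymer) engage.
    With both rates at zero and no errors, trimming is the identity on
    the output.

    Returns ``(mate1_reads, mate2_reads, provenance)`` where provenance
    lists the source transcript id per pair.
    """
    rng = np.random.default_rng(seed)
    eligible = [t for t in transcripts if len(t.seq) >= insert]
    skipped = len(transcripts) - len(eligible)
    if skipped:
        warnings.warn(
            f"{skipped} transcripts shorter than the insert size {insert} "
            "were skipped by the read simulator",
            stacklevel=2,
        )
    if not eligible:
        raise ValueError("no transcript is long enough for the insert size")
    if weights is None:
        probs = np.full(len(eligible), 1.0 / len(eligible))
    else:
        w = np.array([weights.get(t.id, 0.0) for t in eligible], dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights sum to zero over eligible transcripts")
        probs = w / w.sum()
    reads1: list[Read] = []
    reads2: list[Read] = []
    provenance: list[str] = []
    choices = rng.choice(len(eligible), size=n_pairs, p=probs)
    for i, idx in enumerate(choices):
        t = eligible[idx]
        pos = int(rng.integers(0, len(t.seq) - insert + 1))
        frag = t.seq[pos : pos + insert]
        name = f"sim{i:07d}"
        for mate, raw in ((1, frag[:read_len]), (2, revcomp(frag)[:read_len])):
            seq = _apply_errors(raw, error_rate, rng)
            quals = [40] * len(seq)
            if rng.random() < decay_rate:
                span = min(decay_len, len(seq))
                for j in range(span):
                    frac = (j + 1) / span
                    quals[len(seq) - span + j] = int(
                        round(40 - (40 - decay_floor) * frac)
                    )
            if rng.random() < polya_rate:
                tail = int(rng.integers(11, 16))
                tail = min(tail, len(seq))
                seq = seq[: len(seq) - tail] + "A" * tail
            (reads1 if mate == 1 else reads2).append(
                Read(id=name, seq=seq, quals=quals, mate=mate)
            )
        provenance.append(t.id)
    return reads1, reads2, provenance


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, base in enumerate(chars):
        if rng.random() < rate:
            alt = _NT.replace(base, "") if base in _NT else _NT
            chars[i] = alt[int(rng.integers(0, len(alt)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# BLAST tables
# ---------------------------------------------------------------------------


def simulate_blast_tables(
    gt: GroundTruth,
    db: ReferenceDB,
    decoy_rate: float = 0.5,
    seed: int = 0,
    ohr_range: tuple[float, float] = (0.3, 1.0),
) -> tuple[list[BlastHit], list[BlastHit]]:
    """Forward and reverse 12-column tables consistent with the ground truth.

    Forward: every planted ortholog transcript hits its gene at top
    bitscore (500-550) with the subject span drawn to realize a planted
    ortholog hit ratio (recorded in ``gt.ohr_map``); paralog transcripts
    hit their source gene at 400-500; decoy hits to other genes score
    50-350, strictly below every true hit, so best-hit selection is
    deterministic. Reverse: each gene's top hit is its ortholog
    transcript, with its paralog transcripts as lower-scoring hits.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(db.lengths)
    fwd: list[BlastHit] = []
    rev: list[BlastHit] = []
    by_gene_paralogs: dict[str, list[str]] = {}
    for tid, gene in sorted(gt.paralogs.items()):
        by_gene_paralogs.setdefault(gene, []).append(tid)

    def _fwd_hit(tid: str, gene: str, bitscore: float, record_ohr: bool) -> BlastHit:
        plen = db.lengths[gene]
        target = rng.uniform(*ohr_range)
        span = max(1, int(round(target * plen)))
        span = min(span, plen)
        sstart = int(rng.integers(1, plen - span + 2))
        hit = BlastHit(
            qseqid=tid,
            sseqid=gene,
            pident=float(np.round(rng.uniform(80, 99), 2)),
            length=span,
            mismatch=int(rng.integers(0, 10)),
            gapopen=0,
            qstart=1,
            qend=span * 3,
            sstart=sstart,
            send=sstart + span - 1,
            evalue=float(10.0 ** -rng.uniform(50, 150)),
            bitscore=float(np.round(bitscore, 1)),
        )
        if record_ohr:
            gt.ohr_map[tid] = span / plen
        return hit

    all_coding = sorted(gt.orthology_map) + sorted(gt.paralogs)
    for tid in all_coding:
        if tid in gt.orthology_map:
            gene = gt.orthology_map[tid]
            fwd.append(_fwd_hit(tid, gene, rng.uniform(500, 550), True))
        else:
            gene = gt.paralogs[tid]
            fwd.append(_fwd_hit(tid, gene, rng.uniform(400, 500), False))
        n_decoys = int(rng.binomial(3, decoy_rate))
        others = [g for g in genes if g != gene]
        for g in rng.choice(others, size=min(n_decoys, len(others)), replace=False):
            fwd.append(_fwd_hit(tid, str(g), rng.uniform(50, 350), False))

    ortholog_of = {gene: tid for tid, gene in gt.orthology_map.items()}
    for gene in genes:
        tid = ortholog_of.get(gene)
        if tid is None:
            continue
        rev.append(_rev_hit(gene, tid, rng.uniform(500, 550), rng))
        for ptid in by_gene_paralogs.get(gene, []):
            rev.append(_rev_hit(gene, ptid, rng.uniform(50, 450), rng))
    return fwd, rev


def _rev_hit(
    gene: str, tid: str, bitscore: float, rng: np.random.Generator
) -> BlastHit:
    span = int(rng.integers(50, 200))
    return BlastHit(
        qseqid=gene,
        sseqid=tid,
        pident=float(np.round(rng.uniform(80, 99), 2)),
        length=span,
        mismatch=int(rng.integers(0, 10)),
        gapopen=0,
        qstart=1,
        qend=span,
        sstart=1,
        send=span * 3,
        evalue=float(10.0 ** -rng.uniform(50, 150)),
        bitscore=float(np.round(bitscore, 1)),
    )


# ---------------------------------------------------------------------------
# count libraries with planted exclusivity
# ---------------------------------------------------------------------------


def simulate_counts(
    transcripts: Union[Sequence[Transcript], Mapping[str, int]],
    totals_a: int = 331_060_788,
    totals_b: int = 292_205_142,
    n_exclusive_a: int = 29,
    n_exclusive_b: int = 918,
    exclusive_floor: int = 1500,
    dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[list[CountRecord], list[CountRecord], tuple[list[str], list[str]]]:
    """Two count libraries with planted stage-exclusive transcripts.

    Default library totals and the 29/918 exclusive split mirror an
    embryonic/post-embryonic two-library design. Exclusive transcripts
    get exactly zero counts in the silent library and a mean of at least
    ``exclusive_floor`` (default 1500, which stays above a 1000-read
    threshold after library-size correction) in the other; all remaining
    transcripts share the residual library mass via lognormal weights
    scaled in proportion in both libraries. Counts are negative-binomial
    around the planted means; ``dispersion`` 0 gives the rounded means
    exactly.

    Returns ``(records_a, records_b, (exclusive_a_ids, exclusive_b_ids))``.
    """
    if isinstance(transcripts, Mapping):
        lengths = dict(transcripts)
    else:
        lengths = {t.id: len(t.seq) for t in transcripts}
    ids = sorted(lengths)
    n = len(ids)
    if n_exclusive_a + n_exclusive_b > n:
        raise ValueError("more exclusive transcripts requested than transcripts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    excl_a = [ids[i] for i in order[:n_exclusive_a]]
    excl_b = [ids[i] for i in order[n_exclusive_a : n_exclusive_a + n_exclusive_b]]
    shared = [ids[i] for i in order[n_exclusive_a + n_exclusive_b :]]

    means_a = {t: 0.0 for t in ids}
    means_b = {t: 0.0 for t in ids}
    for t in excl_a:
        means_a[t] = exclusive_floor * rng.uniform(1.0, 3.0)
    for t in excl_b:
        means_b[t] = exclusive_floor * rng.uniform(1.0, 3.0)
    rest_a = totals_a - sum(means_a.values())
    rest_b = totals_b - sum(means_b.values())
    if rest_a <= 0 or rest_b <= 0:
        raise ValueError("library totals too small for the exclusive floor")
    if shared:
        w = rng.lognormal(mean=0.0, sigma=1.0, size=len(shared))
        w /= w.sum()
        for t, wi in zip(shared, w):
            means_a[t] = wi * rest_a
            means_b[t] = wi * rest_b

    def draw(mean: float) -> int:
        if mean <= 0:
            return 0
        if dispersion <= 0:
            return int(round(mean))
        size = 1.0 / dispersion
        p = size / (size + mean)
        return int(rng.negative_binomial(size, p))

    records_a = [CountRecord(t, lengths[t], draw(means_a[t])) for t in ids]
    records_b = [CountRecord(t, lengths[t], draw(means_b[t])) for t in ids]
    return records_a, records_b, (excl_a, excl_b)


# ---------------------------------------------------------------------------
# one-call fixture tree
# ---------------------------------------------------------------------------


def simulate_all(
    outdir: PathLike,
    seed: int = 42,
    n_genes: int = 50,
    n_loci: int = 250,
    isoforms_per_locus: int = 2,
    n_pairs: int = 20_000,
    totals_a: int = 3_000_000,
    totals_b: int = 2_700_000,
    n_exclusive_a: int = 5,
    n_exclusive_b: int = 20,
) -> GroundTruth:
    """Generate a complete fixture tree (FASTA/FASTQ/TSV + ground truth JSON).

    The default shape — a 50-gene proteome, 250 loci x 2 isoforms = 500
    transcripts, 20k read pairs — is sized so the full pipeline runs end
    to end in seconds while every stage still has non-trivial input.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    proteins, db = make_reference_proteome(n_genes, seed=sub())
    transcripts, gt = make_transcriptome(
        proteins, n_loci=n_loci, isoforms_per_locus=isoforms_per_locus, seed=sub()
    )
    reads1, reads2, provenance = simulate_reads(
        transcripts, n_pairs=n_pairs, seed=sub()
    )
    gt.read_provenance["pool"] = provenance
    fwd, rev = simulate_blast_tables(gt, db, seed=sub())
    counts_a, counts_b, (excl_a, excl_b) = simulate_counts(
        transcripts,
        totals_a=totals_a,
        totals_b=totals_b,
        n_exclusive_a=n_exclusive_a,
        n_exclusive_b=n_exclusive_b,
        seed=sub(),
    )
    gt.exclusive_a = excl_a
    gt.exclusive_b = excl_b

    write_fasta(proteins, out / "proteome.fasta")
    db.to_tsv(out / "ref_meta.tsv")
    write_fasta(((t.id, t.seq) for t in transcripts), out / "transcripts.fasta")
    write_fastq(reads1, out / "reads_1.fastq")
    write_fastq(reads2, out / "reads_2.fastq")
    write_blast_tab(fwd, out / "fwd.blast6")
    write_blast_tab(rev, out / "rev.blast6")
    write_counts_tsv(counts_a, out / "counts_a.tsv")
    write_counts_tsv(counts_b, out / "counts_b.tsv")
    gt.to_json(out / "ground_truth.json")
    return gt
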