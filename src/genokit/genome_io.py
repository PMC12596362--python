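"""Genome and annotation I/O plus gene-associated sequence extraction.

This module reads genome FASTA files with indexed region access (pyfaidx),
parses GFF3 annotation into a gene -> transcript -> exon/CDS/UTR hierarchy,
and extracts promoters, full-length genes, UTRs, exons and coding sequences.
It also computes windowed genomic tracks (GC content, k-mer counts, gene
density) emitted as BED5, and summary statistics for FASTA/FASTQ files.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  GFF3 on disk is 1-based
inclusive and converted on parse; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Iterator

import gffutils
import pyfaidx
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "GeneModel",
    "TranscriptModel",
    "TrackRecord",
    "SeqStats",
    "load_genome",
    "parse_gff",
    "list_feature_types",
    "extract_feature",
    "revcomp",
    "translate",
    "windowed_tracks",
    "write_bed",
    "seq_stats",
]

FEATURE_KINDS = ("gene", "cds", "exon", "utr5", "utr3", "promoter")

_COMPLEMENT = str.maketrans(
    "ACGTUacgtuRYKMBVDHrykmbvdhSWNswn-",
    "TGCAAtgcaaYRMKVBHDyrmkvbhdSWNswn-",
)
_IUPAC = set("ACGTURYKMSWBDHVNacgturykmswbdhvn-")


# ---------------------------------------------------------------------------
# Genome


class Genome:
    """Indexed, region-specific access to a genome FASTA (no full load).

    Thin wrapper over :class:`pyfaidx.Fasta`; sequence ids are the header
    tokens before the first whitespace.
    """

    def __init__(self, fasta_path: str | os.PathLike):
        try:
            self._fa = pyfaidx.Fasta(str(fasta_path))
        except (pyfaidx.FastaIndexingError, ValueError) as exc:
            raise ValueError(f"cannot index FASTA {fasta_path}: {exc}") from exc
        if len(self._fa.keys()) == 0:
            raise ValueError(f"FASTA {fasta_path} contains no records")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fa.items()}

    def contigs(self) -> list[str]:
        return list(self._fa.keys())

    def __contains__(self, seqid: str) -> bool:
        return seqid in self._fa

    def region(self, seqid: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` on *seqid* (0-based half-open)."""
        if seqid not in self._fa:
            raise KeyError(f"unknown sequence id {seqid!r}")
        n = len(self._fa[seqid])
        if not (0 <= start < end <= n):
            raise ValueError(
                f"region [{start}, {end}) out of bounds for {seqid} (length {n})"
            )
        return str(self._fa[seqid][start:end])

    def sequence(self, seqid: str) -> str:
        return self.region(seqid, 0, self.lengths[seqid])


def load_genome(fasta_path: str | os.PathLike) -> Genome:
    """Open *fasta_path* for lazy region access.

    Raises ``ValueError`` for an empty file or duplicate headers (the
    duplicated id is named in the message).
    """
    return Genome(fasta_path)


# ---------------------------------------------------------------------------
# Annotation model


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    seqid: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    utr5_segments: list[tuple[int, int]] = field(default_factory=list)
    utr3_segments: list[tuple[int, int]] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class GeneModel:
    gene_id: str
    seqid: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    def representative_transcript(self) -> TranscriptModel | None:
        """Transcript with the longest CDS (ties: longest span, then id)."""
        if not self.transcripts:
            return None
        return max(
            self.transcripts,
            key=lambda t: (t.cds_length(), t.span[1] - t.span[0], t.transcript_id),
        )


@dataclass
class TrackRecord:
    seqid: str
    start: int
    end: int
    name: str
    value: float
    flag: str | None = None  # e.g. "all_N" for windows with no callable bases


# ---------------------------------------------------------------------------
# GFF3 parsing

_GENE_TYPES = {"gene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}
_UTR5_TYPES = {"five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR"}


def _prevalidate_gff(gff_path: str | os.PathLike) -> None:
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(f"{gff_path}:{lineno}: non-numeric coordinates")
            if start > end:
                raise ValueError(
                    f"{gff_path}:{lineno}: start > end ({start} > {end})"
                )


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out

def _subtract(ivs: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Parts of *ivs* outside [lo, hi)."""
    out = []
    for s, e in ivs:
        if e <= lo or s >= hi:
            out.append((s, e))
        else:
            if s < lo:
                out.append((s, lo))
            if e > hi:
                out.append((hi, e))
    return out


def parse_gff(gff_path: str | os.PathLike) -> list[GeneModel]:
    """Parse GFF3 into :class:`GeneModel` hierarchies.

    On-disk 1-based inclusive coordinates become 0-based half-open.  When a
    transcript has exon and CDS rows but no explicit UTR rows, 5'/3' UTRs are
    inferred as the exonic sequence outside the CDS span; explicit
    five_prime_UTR / three_prime_UTR rows take precedence.  Children citing
    an unknown Parent are skipped with a logged warning.
    """
    _prevalidate_gff(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )

    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type(tuple(_GENE_TYPES)):
        genes[g.id] = GeneModel(
            gene_id=g.id, seqid=g.seqid, strand=g.strand, span=(g.start - 1, g.end)
        )

    for t in db.features_of_type(tuple(_TRANSCRIPT_TYPES)):
        parents = t.attributes.get("Parent", [])
        parent = parents[0] if parents else None
        if parent is None or parent not in genes:
            log.warning(
                "transcript %s cites unknown Parent %r; skipped", t.id, parent
            )
            continue
        gene = genes[parent]
        tr = TranscriptModel(
            transcript_id=t.id,
            gene_id=parent,
            seqid=t.seqid,
            strand=t.strand,
            span=(t.start - 1, t.end),
        )
        explicit_utr = False
        for child in db.children(t.id):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                tr.exons.append(iv)
            elif child.featuretype == "CDS":
                tr.cds_segments.append(iv)
            elif child.featuretype in _UTR5_TYPES:
                tr.utr5_segments.append(iv)
                explicit_utr = True
            elif child.featuretype in _UTR3_TYPES:
                tr.utr3_segments.append(iv)
                explicit_utr = True
        tr.exons = _merge_intervals(tr.exons)
        tr.cds_segments = _merge_intervals(tr.cds_segments)
        tr.utr5_segments = _merge_intervals(tr.utr5_segments)
        tr.utr3_segments = _merge_intervals(tr.utr3_segments)
        if not explicit_utr and tr.exons and tr.cds_segments:
            cds_lo = tr.cds_segments[0][0]
            cds_hi = tr.cds_segments[-1][1]
            outside = _subtract(tr.exons, cds_lo, cds_hi)
            left = [iv for iv in outside if iv[1] <= cds_lo]
            right = [iv for iv in outside if iv[0] >= cds_hi]
            if tr.strand == "-":
                tr.utr5_segments, tr.utr3_segments = right, left
            else:
                tr.utr5_segments, tr.utr3_segments = left, right
        gene.transcripts.append(tr)

    # orphan exon/CDS rows whose Parent is not a known transcript
    known_tr = {tr.transcript_id for g in genes.values() for tr in g.transcripts}
    for ft in ("exon", "CDS"):
        for child in db.features_of_type(ft):
            parents = child.attributes.get("Parent", [])
            if parents and parents[0] not in known_tr:
                log.warning(
                    "%s at %s:%d cites unknown Parent %r; skipped",
                    ft, child.seqid, child.start, parents[0],
                )
    return list(genes.values())


def list_feature_types(gff_path: str | os.PathLike) -> set[str]:
    """Distinct GFF column-3 feature types present in the file."""
    return set(iter_feature_types(gff_path))


def iter_feature_types(gff_path: str | os.PathLike) -> list[str]:
    """Feature types in file order of first appearance."""
    seen: dict[str, None] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) >= 3:
                seen.setdefault(cols[2], None)
    return list(seen)


# ---------------------------------------------------------------------------
# Sequence operations


def revcomp(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support; case preserved."""
    for i, c in enumerate(seq):
        if c not in _IUPAC:
            raise ValueError(f"non-IUPAC character {c!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds_seq: str) -> str:
    """Translate a CDS in frame 0 with the standard table.

    Stops at the first stop codon (not emitted).  A trailing partial codon is
    ignored with a warning; the minimum input length is one full codon.
    """
    if len(cds_seq) < 3:
        raise ValueError(f"CDS of length {len(cds_seq)} is shorter than one codon")
    trimmed = len(cds_seq) % 3
    if trimmed:
        log.warning("CDS length %d not a multiple of 3; trailing %d base(s) ignored",
                    len(cds_seq), trimmed)
        cds_seq = cds_seq[: len(cds_seq) - trimmed]
    return str(Seq(cds_seq).translate(to_stop=True))


def _segments_for(model: GeneModel | TranscriptModel, kind: str):
    if isinstance(model, GeneModel):
        tr = model.representative_transcript()
    else:
        tr = model
    if kind == "exon":
        return tr.exons if tr else []
    if kind == "cds":
        return tr.cds_segments if tr else []
    if kind == "utr5":
        return tr.utr5_segments if tr else []
    if kind == "utr3":
        return tr.utr3_segments if tr else []
    raise KeyError(kind)


def extract_feature(
    model: GeneModel | TranscriptModel,
    genome: Genome,
    kind: str,
    promoter_len: int = 2000,
) -> tuple[str, str]:
    """Extract one feature sequence as ``(record_id, sequence)``.

    Multi-segment kinds are concatenated in ascending genomic order and
    reverse-complemented once if the model is on the minus strand.  The
    promoter is ``promoter_len`` bases immediately upstream of the
    transcription start (strand-aware), truncated at the contig edge.  Raises
    ``ValueError`` when the requested kind is absent from the model.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}; expected one of {FEATURE_KINDS}")
    gene_id = model.gene_id if isinstance(model, GeneModel) else model.transcript_id
    seqid, strand = model.seqid, model.strand
    if seqid not in genome:
        raise KeyError(f"sequence {seqid!r} not in genome")

    if kind == "gene":
        seq = genome.region(seqid, *model.span)
    elif kind == "promoter":
        if promoter_len <= 0:
            raise ValueError("promoter_len must be positive")
        contig_len = genome.lengths[seqid]
        if strand == "-":
            start, end = model.span[1], min(model.span[1] + promoter_len, contig_len)
        else:
            start, end = max(0, model.span[0] - promoter_len), model.span[0]
        if start >= end:
            raise ValueError(f"{gene_id}: no upstream sequence for promoter")
        seq = genome.region(seqid, start, end)
    else:
        segments = _segments_for(model, kind)
        if not segments:
            raise ValueError(f"{gene_id}: no {kind} segments in model")
        seq = "".join(genome.region(seqid, s, e) for s, e in sorted(segments))
    if strand == "-":
        seq = revcomp(seq)
    return f"{gene_id}|{kind}", seq


def extract_features_batch(
    models: Iterable[GeneModel | TranscriptModel],
    genome: Genome,
    kind: str,
    promoter_len: int = 2000,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Batch extraction; per-record failures are collected, the batch continues.

    Returns ``(records, errors)`` where errors are ``(model_id, message)``.
    """
    records, errors = [], []
    for m in models:
        mid = m.gene_id if isinstance(m, GeneModel) else m.transcript_id
        try:
            records.append(extract_feature(m, genome, kind, promoter_len))
        except (ValueError, KeyError) as exc:
            errors.append((mid, str(exc)))
    return records, errors


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Windowed tracks


def _tile(length: int, window_bp: int) -> Iterator[tuple[int, int]]:
    for s in range(0, length, window_bp):
        yield s, min(s + window_bp, length)


def windowed_tracks(
    genome: Genome,
    metric: str,
    window_bp: int,
    annotation: list[GeneModel] | None = None,
    motif: str | None = None,
) -> list[TrackRecord]:
    """Tile each contig with fixed windows and score one metric per window.

    metric 'gc': (G+C) / callable bases, N excluded from the denominator
    (all-N windows score 0 and are flagged); 'kmer': exact occurrences of
    *motif* whose start lies in the window, overlaps counted; 'gene_density':
    number of genes whose start coordinate lies in the window.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if metric == "kmer":
        if not motif:
            raise ValueError("kmer metric requires a motif")
        if len(motif) > window_bp:
            raise ValueError(f"k={len(motif)} exceeds window size {window_bp}")
        motif = motif.upper()
    if metric == "gene_density" and annotation is None:
        raise ValueError("gene_density requires an annotation")

    starts_by_seqid: dict[str, list[int]] = {}
    if annotation is not None:
        for g in annotation:
            starts_by_seqid.setdefault(g.seqid, []).append(g.span[0])

    out: list[TrackRecord] = []
    for seqid, length in genome.lengths.items():
        seq = genome.sequence(seqid).upper() if metric in ("gc", "kmer") else ""
        for idx, (ws, we) in enumerate(_tile(length, window_bp)):
            name = f"{seqid}_w{idx}"
            if metric == "gc":
                win = seq[ws:we]
                denom = len(win) - win.count("N")
                if denom == 0:
                    out.append(TrackRecord(seqid, ws, we, name, 0.0, flag="all_N"))
                else:
                    gc = (win.count("G") + win.count("C")) / denom
                    out.append(TrackRecord(seqid, ws, we, name, gc))
            elif metric == "kmer":
                count, pos = 0, seq.find(motif, ws)
                while 0 <= pos < we:
                    count += 1
                    pos = seq.find(motif, pos + 1)
                out.append(TrackRecord(seqid, ws, we, name, float(count)))
            elif metric == "gene_density":
                n = sum(1 for s in starts_by_seqid.get(seqid, []) if ws <= s < we)
                out.append(TrackRecord(seqid, ws, we, name, float(n)))
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return out


def write_bed(tracks: list[TrackRecord], path: str | os.PathLike) -> None:
    """Write tracks as BED5 (chrom, start, end, name, value)."""
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(f"{t.seqid}\t{t.start}\t{t.end}\t{t.name}\t{t.value:g}\n")


# ---------------------------------------------------------------------------
# FASTA/FASTQ summary


@dataclass
class SeqStats:
    n_records: int
    total_bp: int
    min_len: int
    max_len: int
    mean_len: float
    gc_fraction: float
    n50: int
    fmt: str


def _n50(lengths: list[int]) -> int:
    """Smallest length such that contigs at least that long hold >= half the bases."""
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc * 2 >= total:
            return ln
    return 0


def seq_stats(path: str | os.PathLike) -> SeqStats:
    """Summary statistics for a FASTA or FASTQ file (format auto-detected)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ (first character {first!r})")
    lengths: list[int] = []
    gc = at = 0
    for rec in SeqIO.parse(str(path), fmt):
        s = str(rec.seq).upper()
        lengths.append(len(s))
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T") + s.count("U")
    if not lengths:
        raise ValueError(f"{path}: no records")
    return SeqStats(
        n_records=len(lengths),
        total_bp=sum(lengths),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=mean(lengths),
        gc_fraction=gc / (gc + at) if gc + at else 0.0,
        n50=_n50(lengths),
        fmt=fmt,
    )
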