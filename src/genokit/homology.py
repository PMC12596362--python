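"""Protein homolog-pair production/filtering and representative-transcript selection.

Homologous gene pairs normally come from an external all-against-all protein
aligner emitting the standard 12-column tabular format; :func:`builtin_align`
provides a desk-scale in-process local aligner (BLOSUM62, affine gaps) so the
whole pipeline runs without third-party binaries.

The longest-representative-transcript workflow aligns transcript sequences
against per-locus CDS templates, keeps matches passing identity (default
>=90%) and template coverage (default >=50%) thresholds, groups qualifying
matches by locus (template id up to its last underscore) and reports the
longest qualifying transcript per locus plus a per-locus match-density table.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

log = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "HomologPair",
    "TranscriptMatch",
    "parse_alignment_table",
    "builtin_align",
    "filter_homologs",
    "filter_transcript_matches",
    "longest_representative_transcripts",
    "gene_key",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One row of 12-column tabular pairwise-alignment output."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity {self.identity_pct} outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    bit_score: float

    def unordered(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class TranscriptMatch:
    transcript_id: str
    gene_id: str
    identity_pct: float
    coverage_pct: float
    transcript_len: int


# ---------------------------------------------------------------------------
# 12-column table I/O


def parse_alignment_table(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Read a tab-separated 12-column alignment table.

    Lines with fewer than 12 columns are skipped with a warning; the count of
    skipped lines is logged.
    """
    records: list[AlignmentRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                skipped += 1
                log.warning("%s:%d: %d columns (<12); skipped", path, lineno, len(cols))
                continue
            try:
                records.append(
                    AlignmentRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        identity_pct=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        e_value=float(cols[10]),
                        bit_score=float(cols[11]),
                    )
                )
            except ValueError as exc:
                skipped += 1
                log.warning("%s:%d: unparsable row (%s); skipped", path, lineno, exc)
    if skipped:
        log.warning("%s: %d malformed line(s) skipped", path, skipped)
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.identity_pct:.1f}\t{r.align_len}\t"
                f"{r.mismatches}\t{r.gap_opens}\t{r.q_start}\t{r.q_end}\t"
                f"{r.s_start}\t{r.s_end}\t{r.e_value:.2g}\t{r.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Built-in local aligner

_PROTEIN_MATRIX = substitution_matrices.load("BLOSUM62")


def _make_aligner(scoring: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    if scoring == "protein":
        # community defaults: BLOSUM62, gap open 11 / extend 1
        aligner.substitution_matrix = _PROTEIN_MATRIX
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    elif scoring == "nucleotide":
        # megablast-like scores at desk scale
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
    else:
        raise ValueError(f"unknown scoring {scoring!r}")
    return aligner


def builtin_align(
    seq_a: str,
    seq_b: str,
    scoring: str = "protein",
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentRecord | None:
    """Local alignment with a substitution matrix and affine gap penalties.

    identity_pct = 100 * identical columns / alignment columns (gap columns
    included in the denominator).  Returns ``None`` when no positive-scoring
    alignment exists.  The alignment engine's traceback is deterministic; the
    first optimal alignment is reported.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    alignments = aligner.align(seq_a, seq_b)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    ss, se = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
    return AlignmentRecord(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=identity,
        align_len=columns,
        mismatches=counts.mismatches,
        gap_opens=counts.internal_gaps,
        q_start=qs + 1,
        q_end=qe,
        s_start=ss + 1,
        s_end=se,
        e_value=0.0,
        bit_score=float(alignments.score),
    )


def all_vs_all(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    scoring: str = "protein",
    min_align_cols: int = 30,
) -> list[AlignmentRecord]:
    """Align every sequence of A against every sequence of B (desk scale).

    Local alignments shorter than *min_align_cols* columns are discarded:
    short chance matches between unrelated proteins can reach high identity
    over a handful of residues, and an external aligner would suppress them
    through its significance (e-value) cutoff, which a raw Smith-Waterman
    score does not provide.
    """
    out: list[AlignmentRecord] = []
    for qid, qseq in proteins_a.items():
        for sid, sseq in proteins_b.items():
            rec = builtin_align(qseq, sseq, scoring, query_id=qid, subject_id=sid)
            if rec is not None and rec.align_len >= min_align_cols:
                out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Homolog filtering


def filter_homologs(
    records: Sequence[AlignmentRecord],
    min_identity_pct: float = 60.0,
    best_n: int = 5,
    drop_self: bool = True,
) -> list[HomologPair]:
    """Filter alignment records into homologous gene pairs.

    Self-hits are removed; per query, records are sorted by bit score
    descending and the top *best_n* distinct subjects kept; the identity
    threshold (inclusive, default >=60%) is then applied and unordered pairs
    de-duplicated keeping the best-scoring record.
    """
    if not 0.0 <= min_identity_pct <= 100.0:
        raise ValueError(f"min_identity_pct {min_identity_pct} outside [0, 100]")
    if best_n < 1:
        raise ValueError("best_n must be >= 1")

    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        if drop_self and r.query_id == r.subject_id:
            continue
        by_query.setdefault(r.query_id, []).append(r)

    kept: dict[frozenset[str], HomologPair] = {}
    for qid, recs in by_query.items():
        recs.sort(key=lambda r: (-r.bit_score, r.e_value, r.subject_id))
        subjects_seen: set[str] = set()
        for r in recs:
            if r.subject_id in subjects_seen:
                continue
            if len(subjects_seen) >= best_n:
                break
            subjects_seen.add(r.subject_id)
            if r.identity_pct < min_identity_pct:
                continue
            key = frozenset((r.query_id, r.subject_id))
            pair = HomologPair(r.query_id, r.subject_id, r.identity_pct, r.bit_score)
            if key not in kept or r.bit_score > kept[key].bit_score:
                kept[key] = pair
    return sorted(kept.values(), key=lambda p: (p.gene_a, p.gene_b))


def write_homolog_pairs(pairs: Iterable[HomologPair], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tidentity_pct\tbit_score\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.identity_pct:.1f}\t{p.bit_score:.1f}\n")


# ---------------------------------------------------------------------------
# Longest representative transcript


def gene_key(template_id: str) -> str:
    """Locus id = template id up to the last underscore (whole id if none)."""
    head, sep, _ = template_id.rpartition("_")
    return head if sep else template_id


def filter_transcript_matches(
    matches: Iterable[TranscriptMatch],
    min_identity_pct: float = 90.0,
    min_coverage_pct: float = 50.0,
) -> list[TranscriptMatch]:
    """Keep matches with identity >= *min_identity_pct* and coverage >= *min_coverage_pct*."""
    return [
        m
        for m in matches
        if m.identity_pct >= min_identity_pct and m.coverage_pct >= min_coverage_pct
    ]


def match_transcripts_to_templates(
    transcripts: Mapping[str, str], templates: Mapping[str, str]
) -> list[TranscriptMatch]:
    """Align every transcript against every CDS template (nucleotide scoring).

    Coverage is the aligned fraction of the template: the template-side
    alignment span divided by template length, as a percentage.
    """
    out: list[TranscriptMatch] = []
    for tid, tseq in transcripts.items():
        for cid, cseq in templates.items():
            rec = builtin_align(tseq, cseq, scoring="nucleotide",
                                query_id=tid, subject_id=cid)
            if rec is None:
                continue
            coverage = 100.0 * (rec.s_end - rec.s_start + 1) / len(cseq)
            out.append(
                TranscriptMatch(
                    transcript_id=tid,
                    gene_id=gene_key(cid),
                    identity_pct=rec.identity_pct,
                    coverage_pct=coverage,
                    transcript_len=len(tseq),
                )
            )
    return out


def select_longest_representatives(
    qualifying: Iterable[TranscriptMatch],
) -> tuple[dict[str, TranscriptMatch], pd.DataFrame]:
    """Per locus, pick the longest qualifying transcript.

    Ties on length break lexicographically by transcript id.  Also returns the
    per-locus density table (number of distinct qualifying transcripts).
    """
    by_gene: dict[str, dict[str, TranscriptMatch]] = {}
    for m in qualifying:
        slot = by_gene.setdefault(m.gene_id, {})
        prev = slot.get(m.transcript_id)
        if prev is None or m.identity_pct > prev.identity_pct:
            slot[m.transcript_id] = m
    selection: dict[str, TranscriptMatch] = {}
    rows = []
    for gid in sorted(by_gene):
        members = sorted(
            by_gene[gid].values(), key=lambda m: (-m.transcript_len, m.transcript_id)
        )
        selection[gid] = members[0]
        rows.append({"gene_id": gid, "n_matching_transcripts": len(members)})
    density = pd.DataFrame(rows, columns=["gene_id", "n_matching_transcripts"])
    return selection, density


def longest_representative_transcripts(
    transcripts_fasta: str | os.PathLike,
    cds_fasta: str | os.PathLike,
    min_identity_pct: float = 90.0,
    min_coverage_pct: float = 50.0,
) -> tuple[dict[str, TranscriptMatch], pd.DataFrame, dict[str, str]]:
    """End-to-end longest-representative-transcript selection from FASTA files.

    Returns ``(selection, density_table, sequences)`` where *selection* maps
    locus id to the chosen :class:`TranscriptMatch` and *sequences* holds the
    chosen transcripts' sequences keyed by transcript id.
    """
    transcripts = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(transcripts_fasta), "fasta")}
    templates = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(cds_fasta), "fasta")}
    matches = match_transcripts_to_templates(transcripts, templates)
    qualifying = filter_transcript_matches(matches, min_identity_pct, min_coverage_pct)
    selection, density = select_longest_representatives(qualifying)
    if not selection:
        log.warning("no transcript passed identity >= %s%% and coverage >= %s%%",
                    min_identity_pct, min_coverage_pct)
    chosen = {m.transcript_id: transcripts[m.transcript_id] for m in selection.values()}
    return selection, density, chosen
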