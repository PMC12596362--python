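"""Profile-HMM based gene-family member identification and accuracy scoring.

A family is defined by one or more required profile-HMM domain models (a
composite model: e.g. an auxin-response-factor family requiring both a B3
and an Auxin_resp domain).  Candidate proteins come from a per-domain hit
table in the HMMER3 ``--domtblout`` dialect; a protein is called a member
only if, for EVERY required model, its best per-domain hit passes the
e-value threshold (default 1e-5, inclusive) and model-side domain coverage
strictly greater than 0.80.  The scan itself is delegated to an external
HMMER engine; this module's contract begins at the per-domain table.

Accuracy against planted truth sets is reported as precision = TP/(TP+FP)
and recall = TP/(TP+FN).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO

from .homology import gene_key

log = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "FamilyDefinition",
    "FamilyCall",
    "FamilyMetrics",
    "parse_domtbl",
    "domain_coverage",
    "call_family_members",
    "extract_member_sequences",
    "evaluate_precision_recall",
]


@dataclass(frozen=True)
class DomainHit:
    """One per-domain profile-HMM match (model-side and sequence-side coords)."""

    protein_id: str
    model_name: str
    model_len: int
    e_value: float  # independent (per-domain) e-value
    hmm_from: int  # 1-based inclusive, model coordinates
    hmm_to: int
    ali_from: int  # 1-based inclusive, sequence coordinates
    ali_to: int

    def __post_init__(self):
        if not 1 <= self.hmm_from <= self.hmm_to <= self.model_len:
            raise ValueError(
                f"hmm envelope {self.hmm_from}..{self.hmm_to} invalid for "
                f"model length {self.model_len}"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class FamilyDefinition:
    family_name: str
    required_models: frozenset[str]
    e_value_max: float = 1e-5
    coverage_min: float = 0.8  # strict: coverage must EXCEED this

    def __post_init__(self):
        if not self.required_models:
            raise ValueError("required_models must be non-empty")
        if not 0.0 < self.coverage_min <= 1.0:
            raise ValueError("coverage_min outside (0, 1]")


@dataclass
class FamilyCall:
    family_name: str
    members: set[str]
    evidence: dict[str, dict[str, DomainHit]]  # member -> model -> best hit
    duplicate_notes: dict[str, list[str]] = field(default_factory=dict)
    # representative -> ids of identical-sequence duplicates it stands for


@dataclass(frozen=True)
class FamilyMetrics:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None


# ---------------------------------------------------------------------------
# domtblout parsing

_DOMTBL_NUMERIC_COLS = (2, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21)


def parse_domtbl(path: str | os.PathLike) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table (``hmmsearch --domtblout`` dialect).

    Target = protein, query = model (search orientation).  Rows whose numeric
    fields do not parse are skipped with a warning; parsing of well-formed
    rows is delegated to Biopython's SearchIO hmmsearch3-domtab reader.
    """
    clean_lines: list[str] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                clean_lines.append(line)
                continue
            fields = line.split()
            ok = len(fields) >= 22
            if ok:
                for ci in _DOMTBL_NUMERIC_COLS:
                    try:
                        float(fields[ci])
                    except ValueError:
                        ok = False
                        break
            if not ok:
                skipped += 1
                log.warning("%s:%d: malformed per-domain row; skipped", path, lineno)
                continue
            clean_lines.append(line)
    if skipped:
        log.warning("%s: %d malformed row(s) skipped", path, skipped)

    hits: list[DomainHit] = []
    buf = io.StringIO("".join(clean_lines))
    for qresult in SearchIO.parse(buf, "hmmsearch3-domtab"):
        model_name, model_len = qresult.id, qresult.seq_len
        for hit in qresult:
            for hsp in hit:
                hits.append(
                    DomainHit(
                        protein_id=hit.id,
                        model_name=model_name,
                        model_len=model_len,
                        e_value=hsp.evalue,
                        # SearchIO exposes 0-based half-open; restore 1-based inclusive
                        hmm_from=hsp.query_start + 1,
                        hmm_to=hsp.query_end,
                        ali_from=hsp.hit_start + 1,
                        ali_to=hsp.hit_end,
                    )
                )
    return hits


def domain_coverage(hit: DomainHit) -> float:
    """Fraction of the model's match states spanned by the hit envelope."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.model_len


# ---------------------------------------------------------------------------
# Membership calling


def _qualifies(hit: DomainHit, family: FamilyDefinition) -> bool:
    return hit.e_value <= family.e_value_max and domain_coverage(hit) > family.coverage_min


def best_hits_per_protein(
    hits: Iterable[DomainHit],
) -> dict[str, dict[str, DomainHit]]:
    """Per (protein, model): hit with the lowest per-domain e-value
    (ties: larger coverage, then smaller hmm_from for determinism)."""
    best: dict[str, dict[str, DomainHit]] = {}
    for h in hits:
        slot = best.setdefault(h.protein_id, {})
        cur = slot.get(h.model_name)
        if cur is None:
            slot[h.model_name] = h
            continue
        key_new = (h.e_value, -domain_coverage(h), h.hmm_from)
        key_cur = (cur.e_value, -domain_coverage(cur), cur.hmm_from)
        if key_new < key_cur:
            slot[h.model_name] = h
    return best


def call_family_members(
    hits: Sequence[DomainHit],
    family: FamilyDefinition,
    sequences: Mapping[str, str] | None = None,
) -> FamilyCall:
    """Apply the all-required-domains composite rule.

    A protein is a member iff for every required model its best per-domain
    hit satisfies e-value <= e_value_max and coverage > coverage_min.  When
    *sequences* is provided, members with identical sequences are collapsed
    to one representative (lexicographically smallest id); the duplicates
    are recorded in ``duplicate_notes``.
    """
    known_models = {h.model_name for h in hits}
    missing = family.required_models - known_models
    if missing:
        log.warning(
            "family %s: required model(s) %s absent from the hit table; "
            "no protein can qualify unless hits exist",
            family.family_name, ", ".join(sorted(missing)),
        )
    best = best_hits_per_protein(hits)
    members: set[str] = set()
    evidence: dict[str, dict[str, DomainHit]] = {}
    for protein_id, per_model in best.items():
        ok = all(
            model in per_model and _qualifies(per_model[model], family)
            for model in family.required_models
        )
        if ok:
            members.add(protein_id)
            evidence[protein_id] = {
                m: per_model[m] for m in family.required_models
            }

    duplicate_notes: dict[str, list[str]] = {}
    if sequences is not None:
        by_seq: dict[str, list[str]] = {}
        for pid in sorted(members):
            seq = sequences.get(pid)
            if seq is None:
                continue
            by_seq.setdefault(seq, []).append(pid)
        for ids in by_seq.values():
            if len(ids) > 1:
                rep, dups = ids[0], ids[1:]
                duplicate_notes[rep] = dups
                for d in dups:
                    members.discard(d)
                    evidence.pop(d, None)
    return FamilyCall(family.family_name, members, evidence, duplicate_notes)


def extract_member_sequences(
    call: FamilyCall,
    proteins_fasta: str | os.PathLike,
    out_fasta: str | os.PathLike | None = None,
    out_tsv: str | os.PathLike | None = None,
    all_hits: Sequence[DomainHit] | None = None,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, list[str]]]:
    """Write member sequences and the domain-architecture table.

    When several member isoforms share one gene locus (underscore naming
    rule), only the longest is written; the others are noted.  The
    architecture table lists, per member, every qualifying-model hit
    (all hits of required models when *all_hits* is given, else the stored
    best-hit evidence).
    """
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(proteins_fasta), "fasta")}
    missing = sorted(m for m in call.members if m not in seqs)
    if missing:
        raise ValueError(f"members missing from FASTA: {', '.join(missing)}")

    by_locus: dict[str, list[str]] = {}
    for m in sorted(call.members):
        by_locus.setdefault(gene_key(m), []).append(m)
    written: dict[str, str] = {}
    isoform_notes: dict[str, list[str]] = {}
    for locus, ids in sorted(by_locus.items()):
        ids.sort(key=lambda i: (-len(seqs[i]), i))
        written[ids[0]] = seqs[ids[0]]
        if len(ids) > 1:
            isoform_notes[ids[0]] = ids[1:]
            log.info("locus %s: kept longest isoform %s; dropped %s",
                     locus, ids[0], ", ".join(ids[1:]))

    rows = []
    if all_hits is not None:
        required = {h.model_name for m in call.evidence.values() for h in m.values()}
        for h in all_hits:
            if h.protein_id in written and h.model_name in required:
                rows.append(_arch_row(h))
    else:
        for pid in sorted(written):
            for h in sorted(call.evidence.get(pid, {}).values(), key=lambda h: h.ali_from):
                rows.append(_arch_row(h))
    arch = pd.DataFrame(
        rows,
        columns=["protein_id", "model", "ali_from", "ali_to", "e_value", "coverage"],
    )

    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for pid, seq in sorted(written.items()):
                fh.write(f">{pid}\n{seq}\n")
    if out_tsv is not None:
        arch.to_csv(out_tsv, sep="\t", index=False)
    return written, arch, isoform_notes


def _arch_row(h: DomainHit) -> dict:
    return {
        "protein_id": h.protein_id,
        "model": h.model_name,
        "ali_from": h.ali_from,
        "ali_to": h.ali_to,
        "e_value": h.e_value,
        "coverage": round(domain_coverage(h), 4),
    }


# ---------------------------------------------------------------------------
# Accuracy evaluation


def evaluate_precision_recall(
    predicted: set[str], truth_positive: set[str], truth_negative: set[str]
) -> FamilyMetrics:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN) against planted truth.

    Truth sets must be disjoint and cover every prediction.  Undefined
    ratios (zero denominators) are reported as ``None``, not 0.
    """
    overlap = truth_positive & truth_negative
    if overlap:
        raise ValueError(f"truth sets overlap: {sorted(overlap)[:5]}...")
    stray = predicted - truth_positive - truth_negative
    if stray:
        raise ValueError(
            f"predictions outside the truth universe: {sorted(stray)[:5]}..."
        )
    tp = len(predicted & truth_positive)
    fp = len(predicted & truth_negative)
    fn = len(truth_positive - predicted)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return FamilyMetrics(tp, fp, fn, precision, recall)
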