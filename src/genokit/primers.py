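"""Two-round nested full-length primer design with thermodynamic reporting.

Round 1 designs outer primers anchored strictly inside the 5' and 3' UTRs of
the spliced transcript, so the product spans the whole CDS; candidates are
enumerated over oligo lengths 18-25 nt, hard-filtered on melting temperature
(default target 60 degC, window +/-3, pair difference <= 3) and ranked by a
soft score that also prefers 40-60% GC.  Round 2 derives nested inner
primers literally from the first and last 20 bases of the CDS (the reverse
primer reverse-complemented), amplifying within any round-1 product.

Reported metrics per oligo: melting temperature (Wallace rule below 14 nt,
nearest-neighbor thermodynamics otherwise, 50 mM monovalent salt and 250 nM
oligo), GC percentage, self-complementarity (longest complementary run
between the oligo and itself over all ungapped offsets) and hairpin
potential (longest self-foldback stem with a loop of at least 3 nt).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .genome_io import GeneModel, Genome, TranscriptModel, extract_feature, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "PrimerPair",
    "DesignConstraints",
    "locate_cds_in_mrna",
    "design_round1",
    "design_round2",
    "design_qpcr",
    "primer_metrics",
]

_PAIRS = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PrimerPair:
    round: int  # 1 = outer (UTR-anchored), 2 = nested inner (CDS-terminal)
    fwd_seq: str
    rev_seq: str
    fwd_pos: int  # 0-based start of the forward oligo on the template
    rev_pos: int  # 0-based start of the reverse oligo's binding site
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    self_comp_fwd: int
    self_comp_rev: int
    hairpin_fwd: int
    hairpin_rev: int
    product_len: int

    def __post_init__(self):
        if self.product_len <= 0:
            raise ValueError("product_len must be > 0")
        for gc in (self.gc_fwd, self.gc_rev):
            if not 0.0 <= gc <= 100.0:
                raise ValueError("GC outside [0, 100]")
        if self.round == 2 and (len(self.fwd_seq) != 20 or len(self.rev_seq) != 20):
            raise ValueError("round-2 oligos must be exactly 20 bases")


@dataclass(frozen=True)
class DesignConstraints:
    tm_target: float = 60.0
    tm_window: float = 3.0  # hard |Tm - target| bound per oligo
    max_tm_diff: float = 3.0  # hard |Tm_fwd - Tm_rev| bound
    min_len: int = 18
    max_len: int = 25
    gc_min: float = 40.0  # soft preference band
    gc_max: float = 60.0
    top_n: int = 5


# ---------------------------------------------------------------------------
# Metrics


def _tm(oligo: str) -> float:
    if len(oligo) < 14:
        return float(_mt.Tm_Wallace(oligo))
    return float(_mt.Tm_NN(oligo, Na=50, dnac1=250, dnac2=0))


def _gc_pct(oligo: str) -> float:
    return 100.0 * (oligo.count("G") + oligo.count("C")) / len(oligo)


def self_complementarity(oligo: str) -> int:
    """Longest contiguous complementary run between the oligo and itself.

    The oligo is slid against its own reverse complement at every ungapped
    offset; the score is the longest run of matching (i.e. complementary,
    antiparallel) positions over all offsets.
    """
    s, t = oligo, revcomp(oligo)
    n = len(s)
    best = 0
    for shift in range(-(n - 1), n):
        run = 0
        for i in range(n):
            j = i + shift
            if 0 <= j < n and s[i] == t[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def hairpin_potential(oligo: str, min_loop: int = 3) -> int:
    """Longest self-foldback stem with a loop of at least *min_loop* bases."""
    n = len(oligo)
    best = 0
    for i in range(n):
        for j in range(i + 1, n):
            # stem pairing oligo[i..] with oligo[..j] folding back
            length = 0
            while (
                i + length < n
                and j - length > i + length
                and (j - length) - (i + length) - 1 >= min_loop
                and _PAIRS.get(oligo[i + length]) == oligo[j - length]
            ):
                length += 1
            best = max(best, length)
    return best


def primer_metrics(oligo: str) -> tuple[float, float, int, int]:
    """(tm, gc_pct, self_comp_score, hairpin_score) for one oligo."""
    if len(oligo) < 8:
        raise ValueError(f"oligo of length {len(oligo)} too short (< 8)")
    oligo = oligo.upper()
    return (
        _tm(oligo),
        _gc_pct(oligo),
        self_complementarity(oligo),
        hairpin_potential(oligo),
    )


# ---------------------------------------------------------------------------
# CDS placement


def locate_cds_in_mrna(mrna_seq: str, cds_seq: str) -> tuple[int, int]:
    """0-based half-open span of the unique exact CDS occurrence in the mRNA."""
    if not mrna_seq or not cds_seq:
        raise ValueError("empty sequence")
    matches = [m.start() for m in re.finditer(re.escape(cds_seq.upper()), mrna_seq.upper())]
    if not matches:
        raise ValueError("CDS not found in mRNA")
    if len(matches) > 1:
        raise ValueError("ambiguous CDS placement (multiple occurrences)")
    return matches[0], matches[0] + len(cds_seq)


# ---------------------------------------------------------------------------
# Round 2: nested CDS-terminal primers


def design_round2(cds_seq: str) -> PrimerPair:
    """Nested inner primers: the CDS's first and last 20 bases.

    fwd = cds[0:20]; rev = revcomp(cds[-20:]); product is the whole CDS.
    """
    cds_seq = cds_seq.upper()
    if len(cds_seq) < 40:
        raise ValueError(f"CDS of {len(cds_seq)} bp too short for 20+20 nested primers")
    fwd = cds_seq[:20]
    rev = revcomp(cds_seq[-20:])
    tm_f, gc_f, sc_f, hp_f = primer_metrics(fwd)
    tm_r, gc_r, sc_r, hp_r = primer_metrics(rev)
    return PrimerPair(
        round=2,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_pos=0,
        rev_pos=len(cds_seq) - 20,
        tm_fwd=tm_f,
        tm_rev=tm_r,
        gc_fwd=gc_f,
        gc_rev=gc_r,
        self_comp_fwd=sc_f,
        self_comp_rev=sc_r,
        hairpin_fwd=hp_f,
        hairpin_rev=hp_r,
        product_len=len(cds_seq),
    )


def design_qpcr(cds_seq: str, constraints: DesignConstraints = DesignConstraints(),
                product_range: tuple[int, int] = (80, 200)) -> list[PrimerPair]:
    """Short-amplicon (qPCR-style) pairs entirely inside the CDS.

    A thin constraint preset over the round-1 machinery: both oligos bind
    within the CDS and the product length falls in *product_range*
    (default 80-200 bp).  Ranking and hard constraints are identical to
    round-1 design.
    """
    cds_seq = cds_seq.upper()
    lo, hi = product_range
    if len(cds_seq) < lo:
        raise ValueError(f"CDS of {len(cds_seq)} bp shorter than the minimum product {lo}")
    fwd_cands = _candidates(cds_seq, 0, constraints, reverse=False)
    rev_cands = _candidates(cds_seq, 0, constraints, reverse=True)
    pairs: list[tuple[float, PrimerPair]] = []
    beam = max(constraints.top_n * 5, 20)
    for fs, fpos, fseq, ftm, fgc in fwd_cands[:beam]:
        for rs, rpos, rseq, rtm, rgc in rev_cands[:beam]:
            product_len = (rpos + len(rseq)) - fpos
            if not lo <= product_len <= hi:
                continue
            if abs(ftm - rtm) > constraints.max_tm_diff:
                continue
            pairs.append((
                fs + rs + abs(ftm - rtm) / 3.0,
                PrimerPair(
                    round=1, fwd_seq=fseq, rev_seq=rseq, fwd_pos=fpos, rev_pos=rpos,
                    tm_fwd=ftm, tm_rev=rtm, gc_fwd=fgc, gc_rev=rgc,
                    self_comp_fwd=self_complementarity(fseq),
                    self_comp_rev=self_complementarity(rseq),
                    hairpin_fwd=hairpin_potential(fseq),
                    hairpin_rev=hairpin_potential(rseq),
                    product_len=product_len,
                ),
            ))
    pairs.sort(key=lambda sp: (sp[0], sp[1].fwd_pos, sp[1].rev_pos))
    return [p for _, p in pairs[: constraints.top_n]]


# ---------------------------------------------------------------------------
# Round 1: UTR-anchored outer primers


def _candidates(region: str, offset: int, cons: DesignConstraints, reverse: bool):
    """Enumerate oligos fully inside *region*; positions are template coords.

    For the reverse side the oligo is the reverse complement of the template
    substring (primes the minus strand); its position is the substring start.
    """
    out = []
    for length in range(cons.min_len, cons.max_len + 1):
        for start in range(0, len(region) - length + 1):
            sub = region[start : start + length]
            oligo = revcomp(sub) if reverse else sub
            tm = _tm(oligo)
            if abs(tm - cons.tm_target) > cons.tm_window:
                continue
            gc = _gc_pct(oligo)
            gc_pen = 0.0 if cons.gc_min <= gc <= cons.gc_max else (
                min(abs(gc - cons.gc_min), abs(gc - cons.gc_max)) / 10.0
            )
            score = abs(tm - cons.tm_target) + gc_pen
            out.append((score, offset + start, oligo, tm, gc))
    out.sort(key=lambda c: (c[0], c[1], -len(c[2])))
    return out


def design_round1(
    model: GeneModel | TranscriptModel,
    genome: Genome,
    constraints: DesignConstraints = DesignConstraints(),
) -> list[PrimerPair]:
    """Outer primers anchored in the UTRs so the product spans the full CDS.

    The template is the spliced transcript (5'UTR + CDS + 3'UTR in
    transcription orientation).  Forward candidates live entirely in the
    5'UTR, reverse candidates in the 3'UTR.  Hard constraints: per-oligo
    melting temperature within ``tm_window`` of the target and pair Tm
    difference at most ``max_tm_diff``.  Returns the ``top_n`` pairs ranked
    by combined Tm closeness and GC preference (empty, with a warning, when
    no pair satisfies the hard constraints).
    """
    tr = model.representative_transcript() if isinstance(model, GeneModel) else model
    if tr is None:
        raise ValueError("gene model has no transcript")
    if not tr.utr5_segments or not tr.utr3_segments:
        raise ValueError("no UTR available for round-1 anchoring")
    _, utr5 = extract_feature(tr, genome, "utr5")
    _, utr3 = extract_feature(tr, genome, "utr3")
    _, cds = extract_feature(tr, genome, "cds")
    utr5, utr3, cds = utr5.upper(), utr3.upper(), cds.upper()
    if len(utr5) < constraints.min_len or len(utr3) < constraints.min_len:
        raise ValueError(
            f"UTR shorter than the minimum oligo length "
            f"({len(utr5)} / {len(utr3)} bp vs {constraints.min_len} nt)"
        )
    mrna = utr5 + cds + utr3
    cds_span = locate_cds_in_mrna(mrna, cds) if cds else (len(utr5), len(utr5))

    fwd_cands = _candidates(utr5, 0, constraints, reverse=False)
    rev_cands = _candidates(utr3, len(utr5) + len(cds), constraints, reverse=True)
    if not fwd_cands or not rev_cands:
        log.warning("no oligo satisfies the Tm window; returning no pairs")
        return []

    # pair the best candidates from each side (bounded beam keeps this fast)
    beam = max(constraints.top_n * 5, 20)
    struct: dict[str, tuple[int, int]] = {}

    def _struct(oligo: str) -> tuple[int, int]:
        if oligo not in struct:
            struct[oligo] = (self_complementarity(oligo), hairpin_potential(oligo))
        return struct[oligo]

    pairs: list[tuple[float, PrimerPair]] = []
    for fs, fpos, fseq, ftm, fgc in fwd_cands[:beam]:
        for rs, rpos, rseq, rtm, rgc in rev_cands[:beam]:
            if abs(ftm - rtm) > constraints.max_tm_diff:
                continue
            product_len = (rpos + len(rseq)) - fpos
            sc_f, hp_f = _struct(fseq)
            sc_r, hp_r = _struct(rseq)
            pair = PrimerPair(
                round=1,
                fwd_seq=fseq,
                rev_seq=rseq,
                fwd_pos=fpos,
                rev_pos=rpos,
                tm_fwd=ftm,
                tm_rev=rtm,
                gc_fwd=fgc,
                gc_rev=rgc,
                self_comp_fwd=sc_f,
                self_comp_rev=sc_r,
                hairpin_fwd=hp_f,
                hairpin_rev=hp_r,
                product_len=product_len,
            )
            pairs.append((fs + rs + abs(ftm - rtm) / 3.0, pair))
    if not pairs:
        log.warning("no primer pair satisfies the Tm-difference bound")
        return []
    pairs.sort(key=lambda sp: (sp[0], sp[1].fwd_pos, sp[1].rev_pos))
    top = [p for _, p in pairs[: constraints.top_n]]
    # positional contract: product must span the entire CDS
    for p in top:
        assert p.fwd_pos + len(p.fwd_seq) <= cds_span[0]
        assert p.rev_pos >= cds_span[1]
    return top
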