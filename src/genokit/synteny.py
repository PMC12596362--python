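"""Collinearity (synteny) block detection by anchor chaining.

Homologous gene pairs ("anchors") are placed at gene-rank coordinates on a
chromosome pair and chained by dynamic programming, in the style of MCScanX:
chain score grows by a match score per anchor and pays a gap penalty per
intervening gene rank on either genome.  Inversions are captured by a second
pass over descending subject-side ranks.  Scored chains are emitted greedily
(best chain first, each anchor consumed at most once per orientation pass),
then redundant blocks are pruned by their anchor-pair intersection ratio.

Output is an MCScanX-dialect collinearity text plus a coordinate TSV.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import genome_io, homology

log = logging.getLogger(__name__)

__all__ = [
    "GenePosition",
    "ChainParams",
    "Anchor",
    "SyntenyBlock",
    "index_gene_positions",
    "map_pairs_to_anchors",
    "chain_anchors",
    "filter_overlapping_blocks",
    "validate_block",
    "run_collinearity",
    "concordance",
    "write_collinearity",
    "write_block_coordinates",
]


@dataclass(frozen=True)
class GenePosition:
    gene_id: str
    seqid: str
    rank: int  # 0-based order index along the chromosome, ascending start
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ChainParams:
    """Tunables of the chaining DP (MCScanX-style conventions).

    gap units are intervening gene ranks (rank difference - 1) summed over
    both genomes; bp distances are never used.
    """

    match_score: float = 50.0
    gap_penalty: float = 1.0
    min_block_size: int = 2
    max_gaps: int = 25
    max_overlap_ratio: float = 0.5

    def __post_init__(self):
        if self.gap_penalty < 0:
            raise ValueError("gap_penalty must be >= 0")
        if self.min_block_size < 2:
            raise ValueError("min_block_size must be >= 2")
        if not 0.0 <= self.max_overlap_ratio <= 1.0:
            raise ValueError("max_overlap_ratio outside [0, 1]")


DEFAULT_PARAMS = ChainParams(min_block_size=5)


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int


@dataclass
class SyntenyBlock:
    anchors: list[tuple[str, str]]
    seqid_a: str
    seqid_b: str
    orientation: str  # "plus" | "minus"
    score: float
    bounds_a: tuple[int, int]
    bounds_b: tuple[int, int]
    ranks_a: list[int] = field(default_factory=list)
    ranks_b: list[int] = field(default_factory=list)

    def anchor_pairs(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in self.anchors}


# ---------------------------------------------------------------------------
# Positions and anchors


def index_gene_positions(annotation: Iterable[genome_io.GeneModel]) -> dict[str, GenePosition]:
    """Assign per-chromosome gene ranks by ascending start (ties: gene id)."""
    by_seqid: dict[str, list[genome_io.GeneModel]] = {}
    seen: set[str] = set()
    for g in annotation:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        by_seqid.setdefault(g.seqid, []).append(g)
    positions: dict[str, GenePosition] = {}
    for seqid, genes in by_seqid.items():
        genes.sort(key=lambda g: (g.span[0], g.gene_id))
        for rank, g in enumerate(genes):
            positions[g.gene_id] = GenePosition(
                g.gene_id, seqid, rank, g.span[0], g.span[1], g.strand
            )
    return positions


def map_pairs_to_anchors(
    pairs: Iterable[homology.HomologPair],
    positions_a: dict[str, GenePosition],
    positions_b: dict[str, GenePosition],
) -> dict[tuple[str, str], list[Anchor]]:
    """Group homolog pairs by chromosome pair; unmapped genes drop with a warning."""
    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for p in pairs:
        pa, pb = positions_a.get(p.gene_a), positions_b.get(p.gene_b)
        if pa is None or pb is None:
            # the pair may be stored subject-first
            pa, pb = positions_a.get(p.gene_b), positions_b.get(p.gene_a)
            if pa is None or pb is None:
                log.warning("pair (%s, %s) has no mapped position; dropped",
                            p.gene_a, p.gene_b)
                continue
        grouped.setdefault((pa.seqid, pb.seqid), []).append(
            Anchor(pa.gene_id, pb.gene_id, pa.rank, pb.rank)
        )
    return grouped


# ---------------------------------------------------------------------------
# Chaining DP


def _best_chain(
    anchors: Sequence[Anchor], params: ChainParams, orientation: str
) -> tuple[list[int], float]:
    """Highest-scoring orientation-consistent chain over *anchors*.

    Anchors must be sorted by (rank_a, rank_b).  best(j) = match_score +
    max(0, max_{i < j} best(i) - gap_penalty * (gap_a + gap_b)) where a
    predecessor needs strictly increasing rank_a, strictly increasing
    (plus) or strictly decreasing (minus) rank_b, and both rank gaps
    <= max_gaps.  Returns the member indices of the best chain and its score.
    """
    n = len(anchors)
    best = [params.match_score] * n
    prev = [-1] * n
    for j in range(n):
        aj = anchors[j]
        for i in range(j):
            ai = anchors[i]
            if ai.rank_a >= aj.rank_a:
                continue
            if orientation == "plus":
                if ai.rank_b >= aj.rank_b:
                    continue
                gap_b = aj.rank_b - ai.rank_b - 1
            else:
                if ai.rank_b <= aj.rank_b:
                    continue
                gap_b = ai.rank_b - aj.rank_b - 1
            gap_a = aj.rank_a - ai.rank_a - 1
            if gap_a > params.max_gaps or gap_b > params.max_gaps:
                continue
            cand = params.match_score + best[i] - params.gap_penalty * (gap_a + gap_b)
            # ties prefer extending a chain over starting fresh, then the
            # smallest predecessor index (first seen) — deterministic
            if cand > best[j] or (cand == best[j] and prev[j] == -1):
                best[j] = cand
                prev[j] = i
    if n == 0:
        return [], 0.0
    end = max(range(n), key=lambda j: (best[j], len(_trace(prev, j))))
    chain = _trace(prev, end)
    return chain, best[end]


def _trace(prev: list[int], end: int) -> list[int]:
    out = [end]
    while prev[out[-1]] != -1:
        out.append(prev[out[-1]])
    out.reverse()
    return out


def _emit_blocks_one_orientation(
    anchors: list[Anchor],
    params: ChainParams,
    orientation: str,
    seqid_a: str,
    seqid_b: str,
    positions_a: dict[str, GenePosition],
    positions_b: dict[str, GenePosition],
) -> list[SyntenyBlock]:
    """Greedy chain extraction: best chain first, anchors consumed once.

    After each emission the DP reruns on the unconsumed anchors, so every
    emitted chain is optimal over the anchors still available.
    """
    remaining = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    blocks: list[SyntenyBlock] = []
    while len(remaining) >= params.min_block_size:
        idx, score = _best_chain(remaining, params, orientation)
        if len(idx) < params.min_block_size:
            break
        members = [remaining[i] for i in idx]
        blocks.append(
            _block_from_anchors(members, score, orientation, seqid_a, seqid_b,
                                positions_a, positions_b)
        )
        chosen = set(idx)
        remaining = [a for i, a in enumerate(remaining) if i not in chosen]
    return blocks


def _block_from_anchors(
    members: list[Anchor],
    score: float,
    orientation: str,
    seqid_a: str,
    seqid_b: str,
    positions_a: dict[str, GenePosition],
    positions_b: dict[str, GenePosition],
) -> SyntenyBlock:
    sa = [positions_a[m.gene_a] for m in members]
    sb = [positions_b[m.gene_b] for m in members]
    return SyntenyBlock(
        anchors=[(m.gene_a, m.gene_b) for m in members],
        seqid_a=seqid_a,
        seqid_b=seqid_b,
        orientation=orientation,
        score=score,
        bounds_a=(min(p.start for p in sa), max(p.end for p in sa)),
        bounds_b=(min(p.start for p in sb), max(p.end for p in sb)),
        ranks_a=[m.rank_a for m in members],
        ranks_b=[m.rank_b for m in members],
    )


def chain_anchors(
    grouped: dict[tuple[str, str], list[Anchor]],
    params: ChainParams,
    positions_a: dict[str, GenePosition],
    positions_b: dict[str, GenePosition],
) -> list[SyntenyBlock]:
    """Chain anchors into blocks per chromosome pair, both orientations."""
    blocks: list[SyntenyBlock] = []
    for (sa, sb) in sorted(grouped):
        anchors = grouped[(sa, sb)]
        for orientation in ("plus", "minus"):
            blocks.extend(
                _emit_blocks_one_orientation(
                    anchors, params, orientation, sa, sb, positions_a, positions_b
                )
            )
    return blocks


def chain_score(block: SyntenyBlock, params: ChainParams) -> float:
    """Recompute a block's score from its anchor ranks (validator support)."""
    score = params.match_score
    for k in range(1, len(block.ranks_a)):
        gap_a = block.ranks_a[k] - block.ranks_a[k - 1] - 1
        if block.orientation == "plus":
            gap_b = block.ranks_b[k] - block.ranks_b[k - 1] - 1
        else:
            gap_b = block.ranks_b[k - 1] - block.ranks_b[k] - 1
        score += params.match_score - params.gap_penalty * (gap_a + gap_b)
    return score


def validate_block(block: SyntenyBlock, params: ChainParams) -> None:
    """Raise ``AssertionError`` unless the block satisfies every invariant."""
    assert len(block.anchors) >= params.min_block_size, "block below min size"
    ra, rb = block.ranks_a, block.ranks_b
    assert all(x < y for x, y in zip(ra, ra[1:])), "ranks_a not strictly increasing"
    if block.orientation == "plus":
        assert all(x < y for x, y in zip(rb, rb[1:])), "plus block ranks_b not increasing"
    else:
        assert all(x > y for x, y in zip(rb, rb[1:])), "minus block ranks_b not decreasing"
    for k in range(1, len(ra)):
        assert ra[k] - ra[k - 1] - 1 <= params.max_gaps, "gap_a exceeds max_gaps"
        assert abs(rb[k] - rb[k - 1]) - 1 <= params.max_gaps, "gap_b exceeds max_gaps"
    assert abs(block.score - chain_score(block, params)) < 1e-6, "score mismatch"


# ---------------------------------------------------------------------------
# Overlap filtering


def filter_overlapping_blocks(
    blocks: Sequence[SyntenyBlock], max_overlap_ratio: float
) -> list[SyntenyBlock]:
    """Greedily keep blocks whose anchor-pair overlap with every kept block,
    relative to the smaller block, is at most *max_overlap_ratio*.

    Blocks are visited in descending score order (ties: more anchors, then
    lexicographic chromosome pair).
    """
    if not 0.0 <= max_overlap_ratio <= 1.0:
        raise ValueError(f"max_overlap_ratio {max_overlap_ratio} outside [0, 1]")
    order = sorted(
        blocks,
        key=lambda b: (-b.score, -len(b.anchors), (b.seqid_a, b.seqid_b)),
    )
    kept: list[SyntenyBlock] = []
    kept_pairs: list[set[frozenset[str]]] = []
    for b in order:
        pairs = b.anchor_pairs()
        ok = True
        for other, other_pairs in zip(kept, kept_pairs):
            shared = len(pairs & other_pairs)
            denom = min(len(pairs), len(other_pairs))
            if denom and shared / denom > max_overlap_ratio:
                ok = False
                break
        if ok:
            kept.append(b)
            kept_pairs.append(pairs)
    return kept


# ---------------------------------------------------------------------------
# Concordance


def concordance(
    pairs_test: set[frozenset[str]], pairs_reference: set[frozenset[str]]
) -> float:
    """Fraction of test collinear gene pairs also present in the reference."""
    if not pairs_test:
        log.warning("empty test pair set; concordance reported as 0")
        return 0.0
    return len(pairs_test & pairs_reference) / len(pairs_test)


def block_gene_pairs(blocks: Iterable[SyntenyBlock]) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    for b in blocks:
        out |= b.anchor_pairs()
    return out


# ---------------------------------------------------------------------------
# Output writers (MCScanX dialect + coordinate TSV)


def write_collinearity(blocks: Sequence[SyntenyBlock], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("############### collinearity blocks ###############\n")
        for i, b in enumerate(blocks):
            fh.write(
                f"## Alignment {i}: score={b.score:g} e_value=0 N={len(b.anchors)} "
                f"{b.seqid_a}&{b.seqid_b} {b.orientation}\n"
            )
            for j, (ga, gb) in enumerate(b.anchors):
                fh.write(f"{i}-{j}:\t{ga}\t{gb}\t0\n")


def write_block_coordinates(blocks: Sequence[SyntenyBlock], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "block_id\tseqid_a\tstart_a\tend_a\tseqid_b\tstart_b\tend_b\torientation\n"
        )
        for i, b in enumerate(blocks):
            fh.write(
                f"{i}\t{b.seqid_a}\t{b.bounds_a[0]}\t{b.bounds_a[1]}\t"
                f"{b.seqid_b}\t{b.bounds_b[0]}\t{b.bounds_b[1]}\t{b.orientation}\n"
            )


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _longest_isoform_proteins(
    genome: genome_io.Genome, annotation: list[genome_io.GeneModel]
) -> dict[str, str]:
    """Per gene: extract the longest-CDS isoform's CDS and translate it."""
    proteins: dict[str, str] = {}
    for gene in annotation:
        tr = gene.representative_transcript()
        if tr is None or not tr.cds_segments:
            log.warning("gene %s has no CDS; skipped", gene.gene_id)
            continue
        _, cds = genome_io.extract_feature(tr, genome, "cds")
        try:
            proteins[gene.gene_id] = genome_io.translate(cds)
        except ValueError as exc:
            log.warning("gene %s: %s; skipped", gene.gene_id, exc)
    return proteins


def run_collinearity(
    fasta_a: str | os.PathLike,
    gff_a: str | os.PathLike,
    fasta_b: str | os.PathLike,
    gff_b: str | os.PathLike,
    params: ChainParams = DEFAULT_PARAMS,
    min_identity_pct: float = 60.0,
    best_n: int = 5,
    alignment_table: str | os.PathLike | None = None,
    out_dir: str | os.PathLike | None = None,
) -> list[SyntenyBlock]:
    """Fully automated collinearity pipeline for two annotated genomes.

    Extracts the longest-isoform CDS per gene, translates, finds homolog
    pairs (from a precomputed 12-column table when given, else with the
    built-in aligner), chains anchors per chromosome pair and orientation,
    prunes overlapping blocks, and — when *out_dir* is given — writes the
    MCScanX-dialect collinearity file, the coordinate TSV and intermediate
    artifacts.  Deterministic for fixed inputs and parameters.
    """
    stage = "parse inputs"
    try:
        genome_a = genome_io.load_genome(fasta_a)
        ann_a = genome_io.parse_gff(gff_a)
        genome_b = genome_io.load_genome(fasta_b)
        ann_b = genome_io.parse_gff(gff_b)

        intra = Path(fasta_a).resolve() == Path(fasta_b).resolve() and (
            Path(gff_a).resolve() == Path(gff_b).resolve()
        )

        stage = "extract and translate CDS"
        prot_a = _longest_isoform_proteins(genome_a, ann_a)
        prot_b = prot_a if intra else _longest_isoform_proteins(genome_b, ann_b)

        stage = "homolog alignment"
        if alignment_table is not None:
            records = homology.parse_alignment_table(alignment_table)
        else:
            records = homology.all_vs_all(prot_a, prot_b)
        pairs = homology.filter_homologs(
            records, min_identity_pct=min_identity_pct, best_n=best_n, drop_self=True
        )
        if not pairs:
            log.warning("zero homolog pairs; emitting empty outputs")

        stage = "anchor chaining"
        pos_a = index_gene_positions(ann_a)
        pos_b = pos_a if intra else index_gene_positions(ann_b)
        grouped = map_pairs_to_anchors(pairs, pos_a, pos_b)
        blocks = chain_anchors(grouped, params, pos_a, pos_b)

        stage = "overlap filtering"
        blocks = filter_overlapping_blocks(blocks, params.max_overlap_ratio)
    except Exception as exc:
        raise RuntimeError(f"collinearity pipeline failed at stage '{stage}': {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        work = out / "work"
        work.mkdir(exist_ok=True)
        genome_io.write_fasta(sorted(prot_a.items()), work / "proteins_a.faa")
        genome_io.write_fasta(sorted(prot_b.items()), work / "proteins_b.faa")
        homology.write_alignment_table(records, work / "alignments.tsv")
        homology.write_homolog_pairs(pairs, work / "homolog_pairs.tsv")
        write_collinearity(blocks, out / "collinearity.txt")
        write_block_coordinates(blocks, out / "blocks.tsv")
    return blocks
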