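"""Deterministic synthetic fixtures: annotated genome pairs with planted
syntenic segments, and gene-family benchmarks with planted domain hits.

The genome-pair generator emulates the inputs of a cross-species
collinearity study: two single-chromosome genomes of ORF-bearing gene
models (5'UTR + CDS + 3'UTR, both strands), where genome B carries copied
segments of genome A whose proteins are point-mutated down to a target
identity, optionally in inverted gene order.  The planted anchor pairs and
segment bounds are emitted as truth tables.

The family benchmark emulates a composite positive/negative evaluation set:
positive proteins carry qualifying per-domain hits (e-value <= 1e-6, model
coverage >= 0.9) for every required model of their family; negatives carry
no hit, an incomplete subset of required models, or sub-threshold hits.
Everything is a pure function of the seed: a fixed seed yields
byte-identical files.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import revcomp

__all__ = [
    "FixtureSpec",
    "PlantedSegment",
    "PlantedFamily",
    "GenomePairFixture",
    "FamilyBenchmark",
    "make_genome_pair",
    "make_family_benchmark",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass(frozen=True)
class PlantedSegment:
    n_genes: int = 12
    orientation: str = "forward"  # "forward" | "inverted"
    identity: float = 0.9  # target protein identity of the copies

    def __post_init__(self):
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("planted identity outside (0, 1]")
        if self.orientation not in ("forward", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class PlantedFamily:
    name: str
    required_models: tuple[str, ...]
    n_positives: int = 33

    def __post_init__(self):
        if self.n_positives < 1:
            raise ValueError("n_positives must be >= 1")


# five families echoing a classic plant benchmark: four single-domain
# families and one composite two-domain family (auxin response factors
# require both a B3 and an Auxin_resp domain)
DEFAULT_FAMILIES = (
    PlantedFamily("ABC", ("ABC_tran",)),
    PlantedFamily("ARF", ("B3", "Auxin_resp")),
    PlantedFamily("MADS", ("SRF-TF",)),
    PlantedFamily("NADPH", ("NAD_binding_1",)),
    PlantedFamily("WRKY", ("WRKY",)),
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_genes: int = 30  # background genes per genome (planted copies extra on B)
    cds_codons_range: tuple[int, int] = (100, 250)
    utr_len: int = 60
    intergenic_range: tuple[int, int] = (100, 300)
    planted_segments: tuple[PlantedSegment, ...] = (PlantedSegment(),)
    planted_families: tuple[PlantedFamily, ...] = DEFAULT_FAMILIES
    n_negatives: int = 1000


@dataclass
class _Gene:
    gene_id: str
    strand: str
    protein: str
    cds: str
    utr5: str
    utr3: str
    # filled at layout time (0-based half-open contig coords)
    span: tuple[int, int] = (0, 0)


@dataclass
class GenomePairFixture:
    fasta_a: Path
    gff_a: Path
    fasta_b: Path
    gff_b: Path
    truth_anchors: list[tuple[str, str, int, str]]  # (gene_a, gene_b, segment, orientation)
    truth_anchors_path: Path
    truth_blocks_path: Path
    # planted per-gene parts (transcript orientation), gene_id -> (strand, utr5, cds, utr3)
    parts_a: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)
    parts_b: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)


@dataclass
class FamilyBenchmark:
    proteins_fasta: Path
    domtbl_path: Path
    truth_positive: dict[str, set[str]]  # family name -> ids
    truth_negative: set[str]
    families: tuple[PlantedFamily, ...]


# ---------------------------------------------------------------------------
# Genome pair


def _random_protein(rng: random.Random, n_codons: int) -> str:
    return "M" + "".join(rng.choice(_AA) for _ in range(n_codons - 1))


def _backtranslate(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein) + rng.choice(_STOPS)


def _mutate_protein(rng: random.Random, protein: str, identity: float) -> str:
    out = [protein[0]]  # keep the start methionine
    for aa in protein[1:]:
        if rng.random() < 1.0 - identity:
            out.append(rng.choice([x for x in _AA if x != aa]))
        else:
            out.append(aa)
    return "".join(out)


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _make_gene(rng: random.Random, gene_id: str, spec: FixtureSpec,
               protein: str | None = None) -> _Gene:
    if protein is None:
        protein = _random_protein(rng, rng.randint(*spec.cds_codons_range))
    return _Gene(
        gene_id=gene_id,
        strand=rng.choice("+-"),
        protein=protein,
        cds=_backtranslate(rng, protein),
        utr5=_random_nt(rng, spec.utr_len),
        utr3=_random_nt(rng, spec.utr_len),
    )


def _layout_genome(rng: random.Random, genes: list[_Gene], spec: FixtureSpec) -> str:
    """Place genes left-to-right with random intergenic spacers; fill spans."""
    chunks: list[str] = []
    cursor = 0
    for g in genes:
        spacer = _random_nt(rng, rng.randint(*spec.intergenic_range))
        chunks.append(spacer)
        cursor += len(spacer)
        transcript = g.utr5 + g.cds + g.utr3
        placed = transcript if g.strand == "+" else revcomp(transcript)
        chunks.append(placed)
        g.span = (cursor, cursor + len(placed))
        cursor += len(placed)
    chunks.append(_random_nt(rng, rng.randint(*spec.intergenic_range)))
    return "".join(chunks)


def _gff_rows(gene: _Gene, seqid: str) -> list[str]:
    gs, ge = gene.span[0] + 1, gene.span[1]  # 1-based inclusive
    tid = f"{gene.gene_id}_1"
    u5, cds_len, u3 = len(gene.utr5), len(gene.cds), len(gene.utr3)
    if gene.strand == "+":
        cs, ce = gene.span[0] + u5 + 1, gene.span[0] + u5 + cds_len
    else:
        cs, ce = gene.span[0] + u3 + 1, gene.span[0] + u3 + cds_len
    rows = [
        f"{seqid}\tsim\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\tID={gene.gene_id}",
        f"{seqid}\tsim\tmRNA\t{gs}\t{ge}\t.\t{gene.strand}\t.\tID={tid};Parent={gene.gene_id}",
        f"{seqid}\tsim\texon\t{gs}\t{ge}\t.\t{gene.strand}\t.\tID={tid}.e1;Parent={tid}",
        f"{seqid}\tsim\tCDS\t{cs}\t{ce}\t.\t{gene.strand}\t0\tID={tid}.c1;Parent={tid}",
    ]
    return rows


def _write_genome(path_fa: Path, path_gff: Path, seqid: str, seq: str,
                  genes: list[_Gene]) -> None:
    with open(path_fa, "w") as fh:
        fh.write(f">{seqid}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(path_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\n".join(_gff_rows(g, seqid)) + "\n")


def make_genome_pair(spec: FixtureSpec, out_dir: str | os.PathLike) -> GenomePairFixture:
    """Write genome pair FASTA/GFF3 files and planted-truth tables."""
    total_planted = sum(s.n_genes for s in spec.planted_segments)
    if total_planted > spec.n_genes:
        raise ValueError(
            f"planted segments need {total_planted} source genes but genome A "
            f"has only {spec.n_genes}"
        )
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes_a = [_make_gene(rng, f"ga{i:04d}", spec) for i in range(spec.n_genes)]

    # source windows for the planted segments: consecutive, non-overlapping
    genes_b: list[_Gene] = [_make_gene(rng, f"gb{i:04d}", spec)
                            for i in range(spec.n_genes)]
    truth: list[tuple[str, str, int, str]] = []
    src = 0
    insert_slots = sorted(
        rng.sample(range(len(genes_b) + 1), k=len(spec.planted_segments)), reverse=True
    )
    for seg_idx, seg in enumerate(spec.planted_segments):
        sources = genes_a[src : src + seg.n_genes]
        src += seg.n_genes
        copies: list[_Gene] = []
        for k, source in enumerate(sources):
            mutated = _mutate_protein(rng, source.protein, seg.identity)
            copy = _Gene(
                gene_id=f"gb_s{seg_idx}_{k:02d}",
                strand=rng.choice("+-"),
                protein=mutated,
                cds=_backtranslate(rng, mutated),
                utr5=_random_nt(rng, spec.utr_len),
                utr3=_random_nt(rng, spec.utr_len),
            )
            copies.append(copy)
            truth.append((source.gene_id, copy.gene_id, seg_idx, seg.orientation))
        if seg.orientation == "inverted":
            copies = list(reversed(copies))
        slot = insert_slots[seg_idx]
        genes_b[slot:slot] = copies

    seq_a = _layout_genome(rng, genes_a, spec)
    seq_b = _layout_genome(rng, genes_b, spec)

    fasta_a, gff_a = out / "genomeA.fa", out / "genomeA.gff3"
    fasta_b, gff_b = out / "genomeB.fa", out / "genomeB.gff3"
    _write_genome(fasta_a, gff_a, "chrA1", seq_a, genes_a)
    _write_genome(fasta_b, gff_b, "chrB1", seq_b, genes_b)

    anchors_path = out / "truth_anchors.tsv"
    with open(anchors_path, "w") as fh:
        fh.write("gene_a\tgene_b\tsegment\torientation\n")
        for ga, gb, seg_idx, orient in truth:
            fh.write(f"{ga}\t{gb}\t{seg_idx}\t{orient}\n")

    blocks_path = out / "truth_blocks.tsv"
    span_a = {g.gene_id: g.span for g in genes_a}
    span_b = {g.gene_id: g.span for g in genes_b}
    with open(blocks_path, "w") as fh:
        fh.write("segment\torientation\tstart_a\tend_a\tstart_b\tend_b\n")
        for seg_idx, seg in enumerate(spec.planted_segments):
            members = [t for t in truth if t[2] == seg_idx]
            sa = [span_a[m[0]] for m in members]
            sb = [span_b[m[1]] for m in members]
            fh.write(
                f"{seg_idx}\t{seg.orientation}\t"
                f"{min(s[0] for s in sa)}\t{max(s[1] for s in sa)}\t"
                f"{min(s[0] for s in sb)}\t{max(s[1] for s in sb)}\n"
            )

    return GenomePairFixture(
        fasta_a=fasta_a, gff_a=gff_a, fasta_b=fasta_b, gff_b=gff_b,
        truth_anchors=truth, truth_anchors_path=anchors_path,
        truth_blocks_path=blocks_path,
        parts_a={g.gene_id: (g.strand, g.utr5, g.cds, g.utr3) for g in genes_a},
        parts_b={g.gene_id: (g.strand, g.utr5, g.cds, g.utr3) for g in genes_b},
    )


# ---------------------------------------------------------------------------
# Family benchmark

_DOMTBL_HEADER = (
    "#                                                               --- full sequence --- "
    "-------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   "
    "E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    "
    "to  from    to  acc description of target\n"
)


def _domtbl_row(protein_id: str, prot_len: int, model: str, model_len: int,
                i_evalue: float, hmm_from: int, hmm_to: int, ali_from: int,
                ali_to: int) -> str:
    return (
        f"{protein_id} - {prot_len} {model} - {model_len} "
        f"{i_evalue:.1e} 150.0 0.1 1 1 {i_evalue / 10:.1e} {i_evalue:.1e} 140.0 0.1 "
        f"{hmm_from} {hmm_to} {ali_from} {ali_to} {max(1, ali_from - 2)} "
        f"{min(prot_len, ali_to + 2)} 0.95 synthetic\n"
    )


def make_family_benchmark(spec: FixtureSpec, out_dir: str | os.PathLike) -> FamilyBenchmark:
    """Write the proteins FASTA, the per-domain hit table and truth sets.

    Positives of each family receive qualifying hits (per-domain e-value
    <= 1e-6, model coverage >= 0.9) for all required models.  Negatives
    cycle through three styles: no hit at all, hits for an incomplete
    subset of a composite family's models, and sub-threshold hits (weak
    e-value or shallow coverage).
    """
    if any(f.n_positives < 1 for f in spec.planted_families):
        raise ValueError("every family needs at least one positive")
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_models = sorted({m for f in spec.planted_families for m in f.required_models})
    model_len = {m: rng.randint(80, 300) for m in all_models}
    composite = [f for f in spec.planted_families if len(f.required_models) > 1]

    proteins: dict[str, str] = {}
    rows: list[str] = []
    truth_positive: dict[str, set[str]] = {}

    def _qualifying_row(pid: str, plen: int, model: str, evalue_hi: float = 1e-6):
        mlen = model_len[model]
        cov_len = rng.randint(int(0.9 * mlen) + 1, mlen)
        hmm_from = rng.randint(1, mlen - cov_len + 1)
        hmm_to = hmm_from + cov_len - 1
        ali_from = rng.randint(1, max(1, plen - cov_len))
        ali_to = min(plen, ali_from + cov_len - 1)
        evalue = 10 ** rng.uniform(-40, -6)
        evalue = min(evalue, evalue_hi)
        rows.append(_domtbl_row(pid, plen, model, mlen, evalue,
                                hmm_from, hmm_to, ali_from, ali_to))

    for fam in spec.planted_families:
        ids: set[str] = set()
        for i in range(fam.n_positives):
            pid = f"{fam.name}_m{i:03d}"
            plen = rng.randint(300, 600)
            proteins[pid] = _random_protein(rng, plen)
            for model in fam.required_models:
                _qualifying_row(pid, plen, model)
            ids.add(pid)
        truth_positive[fam.name] = ids

    truth_negative: set[str] = set()
    for i in range(spec.n_negatives):
        pid = f"bg{i:04d}"
        plen = rng.randint(200, 600)
        proteins[pid] = _random_protein(rng, plen)
        truth_negative.add(pid)
        style = i % 3
        if style == 1 and composite:
            # incomplete subset of a composite family's required models
            fam = composite[i % len(composite)]
            model = sorted(fam.required_models)[i % len(fam.required_models)]
            _qualifying_row(pid, plen, model)
        elif style == 2:
            model = all_models[i % len(all_models)]
            mlen = model_len[model]
            if i % 2 == 0:
                # weak e-value, deep coverage
                rows.append(_domtbl_row(pid, plen, model, mlen, 1e-3,
                                        1, mlen, 1, min(plen, mlen)))
            else:
                # strong e-value, shallow coverage (exactly 50% of the model)
                half = mlen // 2
                rows.append(_domtbl_row(pid, plen, model, mlen, 1e-20,
                                        1, half, 1, min(plen, half)))
        # style 0: no hit at all

    proteins_fasta = out / "benchmark_proteins.faa"
    with open(proteins_fasta, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n{proteins[pid]}\n")

    domtbl_path = out / "benchmark_hits.domtbl"
    with open(domtbl_path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        fh.writelines(rows)
        fh.write("#\n# [ok]\n")

    for fam in spec.planted_families:
        with open(out / f"truth_{fam.name}_positives.txt", "w") as fh:
            fh.write("\n".join(sorted(truth_positive[fam.name])) + "\n")
    with open(out / "truth_negatives.txt", "w") as fh:
        fh.write("\n".join(sorted(truth_negative)) + "\n")

    return FamilyBenchmark(
        proteins_fasta=proteins_fasta,
        domtbl_path=domtbl_path,
        truth_positive=truth_positive,
        truth_negative=truth_negative,
        families=spec.planted_families,
    )
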