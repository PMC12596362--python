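"""Shared fixtures: tiny hand-written genomes/annotations and generated ones."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from genokit import fixtures, genome_io


@pytest.fixture
def tmp_fasta(tmp_path: Path):
    def _write(records: dict[str, str], name: str = "genome.fa") -> Path:
        p = tmp_path / name
        with open(p, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return p

    return _write


@pytest.fixture
def tiny_gff(tmp_path: Path):
    """One plus-strand and one minus-strand gene on a 60 bp contig.

    Both genes: exon 11..40, CDS 16..35 (1-based inclusive on disk).
    """
    text = textwrap.dedent("""\
        ##gff-version 3
        chr1\tsrc\tgene\t11\t40\t.\t+\t.\tID=gplus
        chr1\tsrc\tmRNA\t11\t40\t.\t+\t.\tID=gplus_t1;Parent=gplus
        chr1\tsrc\texon\t11\t40\t.\t+\t.\tID=gplus_t1.e;Parent=gplus_t1
        chr1\tsrc\tCDS\t16\t35\t.\t+\t0\tID=gplus_t1.c;Parent=gplus_t1
        chr2\tsrc\tgene\t11\t40\t.\t-\t.\tID=gminus
        chr2\tsrc\tmRNA\t11\t40\t.\t-\t.\tID=gminus_t1;Parent=gminus
        chr2\tsrc\texon\t11\t40\t.\t-\t.\tID=gminus_t1.e;Parent=gminus_t1
        chr2\tsrc\tCDS\t16\t35\t.\t-\t0\tID=gminus_t1.c;Parent=gminus_t1
        """)
    p = tmp_path / "tiny.gff3"
    p.write_text(text)
    return p


@pytest.fixture
def tiny_genome(tmp_fasta):
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 60 bp
    return genome_io.load_genome(tmp_fasta({"chr1": seq, "chr2": seq}, "tiny.fa"))


@pytest.fixture(scope="session")
def genome_pair(tmp_path_factory):
    """Default planted-segment genome pair, built once per session."""
    out = tmp_path_factory.mktemp("pair")
    spec = fixtures.FixtureSpec(seed=11)
    return fixtures.make_genome_pair(spec, out), spec
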