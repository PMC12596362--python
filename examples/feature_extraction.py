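"""Extract gene-associated sequences and windowed genome tracks.

Simulates one annotated genome, then extracts promoters/CDS/UTRs for every
gene, translates a CDS, and computes GC-content windows as a BED-style track.
"""

import tempfile
from pathlib import Path

from genokit import fixtures, genome_io

with tempfile.TemporaryDirectory() as tmp:
    fx = fixtures.make_genome_pair(
        fixtures.FixtureSpec(seed=42, n_genes=10, planted_segments=()), tmp
    )
    genome = genome_io.load_genome(fx.fasta_a)
    genes = genome_io.parse_gff(fx.gff_a)
    print(f"contigs: {genome.lengths}")
    print(f"genes parsed: {len(genes)}, feature types: "
          f"{genome_io.iter_feature_types(fx.gff_a)}\n")

    for kind in ("promoter", "cds", "utr5", "utr3"):
        records, errors = genome_io.extract_features_batch(
            genes, genome, kind, promoter_len=100
        )
        lengths = [len(s) for _, s in records]
        print(f"{kind:9s}: {len(records)} sequences, "
              f"lengths {min(lengths)}-{max(lengths)} bp")

    gene = genes[0]
    _, cds = genome_io.extract_feature(gene, genome, "cds")
    protein = genome_io.translate(cds)
    print(f"\n{gene.gene_id} ({gene.strand} strand): CDS {len(cds)} bp -> "
          f"protein {len(protein)} aa, starts {protein[:12]}...")

    tracks = genome_io.windowed_tracks(genome, "gc", window_bp=2000)
    print(f"\nGC track, 2 kb windows (value = GC fraction, N excluded):")
    for t in tracks[:5]:
        print(f"  {t.seqid}\t{t.start}\t{t.end}\t{t.value:.3f}")

# Promoters are strand-aware upstream windows (truncated at contig edges);
# CDS/UTR sequences are spliced in transcription orientation, so the protein
# always begins with the planted start codon's methionine.
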