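"""Two-round nested primer design for full-length gene amplification.

Round 1 anchors outer primers in the UTRs (product spans the whole CDS);
round 2 derives nested inner primers from the CDS's terminal 20-mers.
"""

import tempfile

from genokit import fixtures, genome_io, primers

with tempfile.TemporaryDirectory() as tmp:
    fx = fixtures.make_genome_pair(
        fixtures.FixtureSpec(seed=42, n_genes=5, planted_segments=()), tmp
    )
    genome = genome_io.load_genome(fx.fasta_a)
    gene = genome_io.parse_gff(fx.gff_a)[0]
    tr = gene.representative_transcript()
    _, cds = genome_io.extract_feature(tr, genome, "cds")

    print(f"gene {gene.gene_id}: CDS {len(cds)} bp\n")

    print("round 1 (outer, UTR-anchored, Tm target 60 C):")
    for i, p in enumerate(primers.design_round1(tr, genome)):
        print(f"  #{i}: fwd {p.fwd_seq} (Tm {p.tm_fwd:.1f}, GC {p.gc_fwd:.0f}%)")
        print(f"       rev {p.rev_seq} (Tm {p.tm_rev:.1f}, GC {p.gc_rev:.0f}%)"
              f"  product {p.product_len} bp")

    p2 = primers.design_round2(cds)
    print(f"\nround 2 (nested, CDS-terminal 20-mers):")
    print(f"  fwd {p2.fwd_seq} = first 20 CDS bases")
    print(f"  rev {p2.rev_seq} = revcomp of last 20 CDS bases")
    print(f"  amplicon = full CDS, {p2.product_len} bp; "
          f"self-complementarity {p2.self_comp_fwd}/{p2.self_comp_rev}, "
          f"hairpin stems {p2.hairpin_fwd}/{p2.hairpin_rev}")

# Every round-1 product contains the round-2 amplicon (nested PCR); the
# self-complementarity and hairpin scores are the longest complementary runs
# in base pairs — small values mean little primer-dimer/hairpin risk.
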