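"""Anchor chaining against an exhaustive enumeration oracle, overlap
filtering against an independent greedy oracle, and the planted-truth
end-to-end pipeline."""

import math
import random

import pytest

from genokit import fixtures, genome_io, synteny
from genokit.synteny import Anchor, ChainParams


# --------------------------------------------------------------------------
# Exhaustive chain-enumeration oracle


def oracle_best_chain(anchors, params, orientation):
    """Best chain by brute-force DFS over every orientation-consistent chain.

    Returns (score, list of all optimal chains as tuples of anchors);
    score is -inf when there are no anchors.
    """
    order = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    best = [-math.inf, []]

    def ok_step(ai, aj):
        if ai.rank_a >= aj.rank_a:
            return None
        gap_a = aj.rank_a - ai.rank_a - 1
        if orientation == "plus":
            if ai.rank_b >= aj.rank_b:
                return None
            gap_b = aj.rank_b - ai.rank_b - 1
        else:
            if ai.rank_b <= aj.rank_b:
                return None
            gap_b = ai.rank_b - aj.rank_b - 1
        if gap_a > params.max_gaps or gap_b > params.max_gaps:
            return None
        return gap_a + gap_b

    def record(chain, score):
        if score > best[0]:
            best[0], best[1] = score, [tuple(chain)]
        elif score == best[0]:
            best[1].append(tuple(chain))

    def dfs(chain, score):
        record(chain, score)
        last = chain[-1]
        for nxt in order:
            gaps = ok_step(last, nxt)
            if gaps is not None:
                dfs(chain + [nxt], score + params.match_score - params.gap_penalty * gaps)

    for a in order:
        dfs([a], params.match_score)
    return best[0], best[1]


def check_emissions_against_oracle(anchors, params):
    """Every emitted block must be the oracle-optimal chain over the anchors
    still unconsumed at its emission, per orientation pass."""
    positions = {}
    pos_a, pos_b = {}, {}
    for a in anchors:
        pos_a[a.gene_a] = synteny.GenePosition(a.gene_a, "cA", a.rank_a, a.rank_a * 10, a.rank_a * 10 + 5, "+")
        pos_b[a.gene_b] = synteny.GenePosition(a.gene_b, "cB", a.rank_b, a.rank_b * 10, a.rank_b * 10 + 5, "+")
    blocks = synteny.chain_anchors({("cA", "cB"): list(anchors)}, params, pos_a, pos_b)
    for orientation in ("plus", "minus"):
        remaining = list(anchors)
        for block in [b for b in blocks if b.orientation == orientation]:
            synteny.validate_block(block, params)
            score, optima = oracle_best_chain(remaining, params, orientation)
            assert block.score == pytest.approx(score), (
                f"{orientation} block score {block.score} != oracle best {score}"
            )
            members = set(zip(block.ranks_a, block.ranks_b))
            if len(optima) == 1:
                assert members == {(a.rank_a, a.rank_b) for a in optima[0]}
            remaining = [a for a in remaining if (a.rank_a, a.rank_b) not in members]
        if remaining:
            score, optima = oracle_best_chain(remaining, params, orientation)
            assert all(len(c) < params.min_block_size for c in optima), (
                f"unemitted {orientation} chain of size >= min_block_size remains"
            )
    return blocks


def random_instance(rng: random.Random, max_anchors: int = 20):
    n = rng.randint(2, max_anchors)
    span = max(4, int(n * rng.uniform(1.0, 2.0)))
    anchors = []
    used = set()
    for i in range(n):
        ra, rb = rng.randrange(span), rng.randrange(span)
        if (ra, rb) in used:
            continue
        used.add((ra, rb))
        anchors.append(Anchor(f"a{i}", f"b{i}", ra, rb))
    params = ChainParams(
        match_score=50.0,
        gap_penalty=rng.choice([0.5, 1.0, 2.0, 5.0]),
        min_block_size=rng.choice([2, 2, 3]),
        max_gaps=rng.choice([2, 3, 25]),
        max_overlap_ratio=0.5,
    )
    return anchors, params


class TestIndexGenePositions:
    def _gene(self, gid, seqid, start):
        return genome_io.GeneModel(gid, seqid, "+", (start, start + 10))

    def test_rank_by_start(self):
        genes = [self._gene("a", "c1", 100), self._gene("b", "c1", 50),
                 self._gene("c", "c1", 200)]
        pos = synteny.index_gene_positions(genes)
        assert [pos[g].rank for g in "abc"] == [1, 0, 2]

    def test_equal_start_ties_by_gene_id(self):
        genes = [self._gene("z", "c1", 50), self._gene("a", "c1", 50)]
        pos = synteny.index_gene_positions(genes)
        assert pos["a"].rank == 0 and pos["z"].rank == 1

    def test_independent_rank_spaces_per_seqid(self):
        genes = [self._gene("a", "c1", 100), self._gene("b", "c2", 100)]
        pos = synteny.index_gene_positions(genes)
        assert pos["a"].rank == pos["b"].rank == 0

    def test_duplicate_gene_id_rejected(self):
        genes = [self._gene("a", "c1", 1), self._gene("a", "c1", 50)]
        with pytest.raises(ValueError, match="duplicate"):
            synteny.index_gene_positions(genes)


class TestChainAnchors:
    def test_perfect_collinear_run_is_one_plus_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, i) for i in range(5)]
        params = ChainParams(min_block_size=5)
        blocks = check_emissions_against_oracle(anchors, params)
        assert len(blocks) == 1
        (b,) = blocks
        assert b.orientation == "plus" and len(b.anchors) == 5
        assert b.score == 5 * params.match_score

    def test_min_block_size_filters_out_short_chains(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, i) for i in range(5)]
        blocks = check_emissions_against_oracle(anchors, ChainParams(min_block_size=6))
        assert blocks == []

    def test_descending_run_is_one_minus_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, 9 - i) for i in range(5)]
        blocks = check_emissions_against_oracle(anchors, ChainParams(min_block_size=5))
        assert len(blocks) == 1 and blocks[0].orientation == "minus"

    def test_gap_penalty_subtracted_per_intervening_rank(self):
        # ranks 0,1 then jump to 4 on both genomes: gaps 2+2
        anchors = [Anchor("a0", "b0", 0, 0), Anchor("a1", "b1", 1, 1),
                   Anchor("a2", "b2", 4, 4)]
        params = ChainParams(match_score=50, gap_penalty=1, min_block_size=2)
        blocks = check_emissions_against_oracle(anchors, params)
        plus = [b for b in blocks if b.orientation == "plus"]
        assert plus[0].score == pytest.approx(3 * 50 - 1 * (2 + 2))

    def test_max_gaps_splits_distant_runs(self):
        anchors = [Anchor(f"a{i}", f"b{i}", i, i) for i in range(3)]
        anchors += [Anchor(f"a{i+10}", f"b{i+10}", i + 10, i + 10) for i in range(3)]
        params = ChainParams(min_block_size=2, max_gaps=3)
        blocks = check_emissions_against_oracle(anchors, params)
        plus = [b for b in blocks if b.orientation == "plus"]
        assert sorted(len(b.anchors) for b in plus) == [3, 3]

    def test_random_instances_match_exhaustive_oracle(self):
        rng = random.Random(1234)
        for _ in range(40):
            anchors, params = random_instance(rng, max_anchors=14)
            check_emissions_against_oracle(anchors, params)

    def test_raising_min_block_size_never_adds_blocks(self):
        rng = random.Random(99)
        anchors, params = random_instance(rng, max_anchors=14)
        pos_a = {a.gene_a: synteny.GenePosition(a.gene_a, "cA", a.rank_a, a.rank_a, a.rank_a + 1, "+") for a in anchors}
        pos_b = {a.gene_b: synteny.GenePosition(a.gene_b, "cB", a.rank_b, a.rank_b, a.rank_b + 1, "+") for a in anchors}
        counts = []
        for mbs in (2, 3, 5, 8):
            p = ChainParams(match_score=50, gap_penalty=1, min_block_size=mbs, max_gaps=25)
            counts.append(len(synteny.chain_anchors({("cA", "cB"): anchors}, p, pos_a, pos_b)))
        assert counts == sorted(counts, reverse=True)


# --------------------------------------------------------------------------
# Overlap filter


def _block(score, pairs, seqids=("cA", "cB")):
    return synteny.SyntenyBlock(
        anchors=list(pairs), seqid_a=seqids[0], seqid_b=seqids[1],
        orientation="plus", score=score, bounds_a=(0, 1), bounds_b=(0, 1),
    )


def oracle_overlap_filter(blocks, ratio):
    """Independent greedy re-implementation of the intersection-ratio rule."""
    order = sorted(blocks, key=lambda b: (-b.score, -len(b.anchors), (b.seqid_a, b.seqid_b)))
    kept = []
    for b in order:
        mine = {frozenset(p) for p in b.anchors}
        if all(
            len(mine & {frozenset(p) for p in k.anchors})
            <= ratio * min(len(mine), len(k.anchors))
            for k in kept
        ):
            kept.append(b)
    return kept


class TestOverlapFilter:
    def test_identical_blocks_keep_first(self):
        b1 = _block(100, [("a1", "b1"), ("a2", "b2")])
        b2 = _block(90, [("a1", "b1"), ("a2", "b2")])
        kept = synteny.filter_overlapping_blocks([b1, b2], 0.5)
        assert kept == [b1]

    def test_disjoint_blocks_both_kept(self):
        b1 = _block(100, [("a1", "b1"), ("a2", "b2")])
        b2 = _block(90, [("a3", "b3"), ("a4", "b4")])
        assert len(synteny.filter_overlapping_blocks([b1, b2], 0.0)) == 2

    def test_randomized_sets_match_independent_oracle(self):
        rng = random.Random(5)
        for _ in range(25):
            universe = [(f"a{i}", f"b{i}") for i in range(12)]
            blocks = [
                _block(rng.randrange(50, 500),
                       rng.sample(universe, rng.randint(2, 8)))
                for _ in range(rng.randint(2, 8))
            ]
            ratio = rng.choice([0.0, 0.3, 0.5, 1.0])
            got = synteny.filter_overlapping_blocks(blocks, ratio)
            want = oracle_overlap_filter(blocks, ratio)
            assert [id(b) for b in got] == [id(b) for b in want]

    def test_zero_ratio_means_anchor_disjoint_blocks(self):
        rng = random.Random(6)
        universe = [(f"a{i}", f"b{i}") for i in range(10)]
        blocks = [
            _block(rng.randrange(50, 500), rng.sample(universe, rng.randint(2, 6)))
            for _ in range(6)
        ]
        kept = synteny.filter_overlapping_blocks(blocks, 0.0)
        seen = set()
        for b in kept:
            assert not (b.anchor_pairs() & seen)
            seen |= b.anchor_pairs()

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            synteny.filter_overlapping_blocks([], 1.5)


class TestConcordance:
    def test_identical_disjoint_and_partial(self):
        pairs = {frozenset((f"a{i}", f"b{i}")) for i in range(10)}
        other = {frozenset((f"a{i}", f"b{i}")) for i in range(5, 15)}
        assert synteny.concordance(pairs, pairs) == 1.0
        assert synteny.concordance(pairs, set()) == 0.0
        assert synteny.concordance(pairs, other) == 0.5

    def test_empty_test_set_is_zero_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            assert synteny.concordance(set(), {frozenset(("a", "b"))}) == 0.0
        assert any("empty" in r.message for r in caplog.records)


# --------------------------------------------------------------------------
# End-to-end planted truth


class TestRunCollinearity:
    def test_forward_planted_segment_recovered_exactly(self, genome_pair):
        fx, _ = genome_pair
        blocks = synteny.run_collinearity(
            fx.fasta_a, fx.gff_a, fx.fasta_b, fx.gff_b,
            params=ChainParams(min_block_size=5),
        )
        assert len(blocks) == 1
        assert blocks[0].orientation == "plus" and len(blocks[0].anchors) == 12
        truth = {frozenset((a, b)) for a, b, _, _ in fx.truth_anchors}
        assert synteny.block_gene_pairs(blocks) == truth

    def test_inverted_planted_segment_is_minus_block(self, tmp_path):
        spec = fixtures.FixtureSpec(
            seed=23, planted_segments=(fixtures.PlantedSegment(12, "inverted", 0.9),)
        )
        fx = fixtures.make_genome_pair(spec, tmp_path / "inv")
        blocks = synteny.run_collinearity(
            fx.fasta_a, fx.gff_a, fx.fasta_b, fx.gff_b,
            params=ChainParams(min_block_size=5),
        )
        assert len(blocks) == 1 and blocks[0].orientation == "minus"
        truth = {frozenset((a, b)) for a, b, _, _ in fx.truth_anchors}
        assert synteny.block_gene_pairs(blocks) == truth

    def test_self_comparison_without_duplications_has_no_blocks(self, genome_pair):
        fx, _ = genome_pair
        blocks = synteny.run_collinearity(
            fx.fasta_a, fx.gff_a, fx.fasta_a, fx.gff_a,
            params=ChainParams(min_block_size=5),
        )
        assert blocks == []

    def test_pipeline_outputs_byte_deterministic(self, genome_pair, tmp_path):
        import filecmp
        fx, _ = genome_pair
        for run in ("r1", "r2"):
            synteny.run_collinearity(
                fx.fasta_a, fx.gff_a, fx.fasta_b, fx.gff_b,
                params=ChainParams(min_block_size=5), out_dir=tmp_path / run,
            )
        for name in ("collinearity.txt", "blocks.tsv", "work/homolog_pairs.tsv"):
            assert filecmp.cmp(tmp_path / "r1" / name, tmp_path / "r2" / name,
                               shallow=False)

    def test_output_files_written(self, genome_pair, tmp_path):
        fx, _ = genome_pair
        out = tmp_path / "out"
        synteny.run_collinearity(
            fx.fasta_a, fx.gff_a, fx.fasta_b, fx.gff_b,
            params=ChainParams(min_block_size=5), out_dir=out,
        )
        text = (out / "collinearity.txt").read_text()
        assert "## Alignment 0:" in text and "e_value=0" in text
        coords = (out / "blocks.tsv").read_text().splitlines()
        assert coords[0].startswith("block_id") and len(coords) == 2
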