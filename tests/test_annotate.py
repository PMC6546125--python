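"""Promoters, window-gene intersection, Monte-Carlo nulls, GO enrichment."""

import numpy as np
import pytest

from matchcomp import (
    CategorySpec,
    GeneModel,
    GoMapping,
    SynthSpec,
    deduplicate,
    genes_in_windows,
    go_enrichment,
    mc_gene_null,
    promoters,
    read_gene2go,
    read_gene_info,
    read_refgene,
    synth_annotation,
)
from matchcomp.annotate import _iter_rng
from matchcomp.synth import write_gene2go, write_gene_info, write_refgene


def gene(symbol, tss, strand="+", record="c", length=5_000):
    if strand == "+":
        return GeneModel(symbol, record, strand, tss, tss + length)
    return GeneModel(symbol, record, strand, max(1, tss - length), tss)


class TestPromoters:
    def test_plus_strand_arithmetic(self):
        (p,) = promoters([gene("g", 10_000)])
        assert (p.start, p.end) == (8_000, 11_999)

    def test_minus_strand_clipped(self):
        (p,) = promoters([gene("g", 500, strand="-")], {"c": 100_000})
        assert (p.start, p.end) == (1, 2_499)

    def test_clipped_at_record_end(self):
        (p,) = promoters([gene("g", 99_500, strand="-")], {"c": 100_000})
        assert (p.start, p.end) == (97_500, 100_000)

    def test_lengths_always_4000_unless_clipped(self):
        rng = np.random.default_rng(0)
        genes = [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(1, 200_000, 200))]
        for p in promoters(genes, {"c": 200_000}):
            clipped = p.start == 1 or p.end == 200_000
            assert clipped or (p.end - p.start + 1 == 4_000)

    def test_tss_outside_record_skipped(self, caplog):
        with caplog.at_level("WARNING", logger="matchcomp"):
            out = promoters([gene("far", 500_000)], {"c": 100_000})
        assert out == [] and "far" in caplog.text


class TestGenesInWindows:
    def test_promoter_inside_window(self):
        proms = promoters([gene("g", 5_000)])
        assert genes_in_windows(proms, [("c", 1, 10_000)]) == {"g"}

    def test_single_base_touch_counts(self):
        proms = promoters([gene("g", 10_000)])  # promoter [8000, 11999]
        assert genes_in_windows(proms, [("c", 11_999, 12_100)]) == {"g"}
        assert genes_in_windows(proms, [("c", 12_000, 12_100)]) == set()

    def test_gene_counted_once_across_windows(self):
        proms = promoters([gene("g", 10_000)])
        wins = [("c", 7_000, 9_000), ("c", 9_001, 12_000)]
        assert genes_in_windows(proms, wins) == {"g"}

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(4)
        genes = [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(3_000, 90_000, 60))]
        proms = promoters(genes, {"c": 100_000})
        wins = [("c", int(s), int(s) + 4_999) for s in rng.integers(1, 95_000, 25)]
        expect = {
            p.symbol for p in proms if any(p.start <= e and p.end >= s for _, s, e in wins)
        }
        assert genes_in_windows(proms, wins) == expect


def grid_windows(L, W, step, record="c"):
    return [(record, s, s + W - 1) for s in range(1, L - W + 2, step)]


class TestMcGeneNull:
    def test_single_iteration_hit_gives_p_one(self):
        proms = promoters([gene("g", 5_000)])
        wins = grid_windows(20_000, 10_000, 1_000)
        res = mc_gene_null(proms, observed=0, n=3, candidate_windows=wins, iterations=1, seed=0)
        assert res.f == 1 and res.p == 1.0 and not res.p_is_floor

    def test_planted_enrichment_hits_floor(self):
        """Genes spread genome-wide: no 5 random windows can reach all 40."""
        L = 500_000
        proms = promoters([gene(f"g{i}", 6_000 + 11_000 * i) for i in range(40)], {"c": L})
        wins = grid_windows(L, 10_000, 1_000)
        res = mc_gene_null(proms, observed=40, n=5, candidate_windows=wins, iterations=10_000, seed=1)
        assert res.p_is_floor
        assert res.p == pytest.approx(1e-4)
        assert res.p_text == "<0.0001"

    def test_uniform_calibration_fold_near_one(self):
        rng = np.random.default_rng(6)
        L = 400_000
        proms = promoters(
            [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(3_000, L - 3_000, 150))],
            {"c": L},
        )
        wins = grid_windows(L, 10_000, 2_000)
        chosen = [wins[i] for i in rng.choice(len(wins), 25, replace=False)]
        observed = genes_in_windows(proms, chosen)
        res = mc_gene_null(proms, len(observed), 25, wins, iterations=400, seed=2)
        assert 0.5 < res.observed / res.expected < 1.6
        assert res.p > 0.01

    def test_too_many_windows_requested(self):
        proms = promoters([gene("g", 5_000)])
        with pytest.raises(ValueError, match="distinct windows"):
            mc_gene_null(proms, 1, 100, grid_windows(20_000, 10_000, 1_000), 10, 0)

    def test_iteration_order_insensitive(self):
        """Per-iteration seeding makes serial and reordered execution identical."""
        proms = promoters([gene(f"g{i}", 4_000 * i + 3_000) for i in range(20)])
        wins = grid_windows(100_000, 10_000, 1_000)
        res = mc_gene_null(proms, observed=5, n=4, candidate_windows=wins, iterations=50, seed=9)
        # recompute iterations in reverse order with the same per-iteration rngs
        from matchcomp.annotate import _overlap_matrix

        sym = {p.symbol: i for i, p in enumerate(proms)}
        ids = np.array([sym[p.symbol] for p in proms])
        wg = [np.unique(ids[a]) for a in _overlap_matrix(proms, wins)]
        total, f = 0.0, 0
        for it in reversed(range(50)):
            rng = _iter_rng(9, it)
            chosen = rng.choice(len(wins), size=4, replace=False)
            cnt = np.unique(np.concatenate([wg[c] for c in chosen])).size
            total += cnt
            f += cnt >= 5
        assert res.expected == pytest.approx(total / 50)
        assert res.f == f


def make_mapping(n_cats=20, size=20):
    gene_to_go = {}
    terms = {}
    for c in range(n_cats):
        cat = f"GO:{c:07d}"
        terms[cat] = (f"process {c}", "Process")
        for k in range(size):
            gene_to_go[f"g{c}_{k}"] = {cat}
    return GoMapping(gene_to_go, terms)


class TestGoEnrichment:
    def test_planted_category_ranks_first(self):
        mapping = make_mapping(n_cats=12, size=60)
        rng = np.random.default_rng(3)
        observed = {f"g0_{k}" for k in range(50)}  # 50 of 60 genes of category 0
        background = [g for g in mapping.gene_to_go if not g.startswith("g0_")]
        observed |= set(rng.choice(background, 30, replace=False))
        res = go_enrichment(observed, mapping, iterations=2_000, seed=0)
        top = res[0]
        assert top.category == "GO:0000000"
        assert top.fold > 3
        assert top.p_is_floor
        assert top.p_bonferroni == pytest.approx(min(1.0, (1 / 2_000) * len(res)))

    def test_min_members_filter(self):
        mapping = make_mapping(n_cats=2, size=15)
        small = "GO:small"
        mapping.terms[small] = ("tiny process", "Process")
        for k in range(9):
            mapping.gene_to_go[f"s{k}"] = {small}
        res = go_enrichment(set(list(mapping.gene_to_go)[:20]), mapping, iterations=50, seed=0)
        assert all(r.category != small for r in res)
        assert all(r.C >= 10 for r in res)

    def test_empty_observed_warns(self, caplog):
        mapping = make_mapping(2, 12)
        with caplog.at_level("WARNING", logger="matchcomp"):
            assert go_enrichment(set(), mapping, iterations=10, seed=0) == []
        assert "universe" in caplog.text

    def test_uniform_observed_pvalues_roughly_uniform(self):
        mapping = make_mapping(n_cats=50, size=20)
        rng = np.random.default_rng(12)
        observed = set(rng.choice(sorted(mapping.gene_to_go), 100, replace=False))
        res = go_enrichment(observed, mapping, iterations=1_000, seed=5)
        ps = np.array([r.p for r in res])
        assert (ps < 0.05).mean() <= 0.12
        assert ps.mean() > 0.3

    def test_determinism_across_runs(self):
        mapping = make_mapping(6, 15)
        observed = set(list(mapping.gene_to_go)[::3])
        a = go_enrichment(observed, mapping, iterations=200, seed=42)
        b = go_enrichment(observed, mapping, iterations=200, seed=42)
        assert [(r.category, r.E, r.f) for r in a] == [(r.category, r.E, r.f) for r in b]

    def test_fold_invariant_to_record_relabeling(self):
        """O/E depends on gene sets only, never on chromosome names."""
        mapping = make_mapping(4, 12)
        observed = set(list(mapping.gene_to_go)[:15])
        res = go_enrichment(observed, mapping, iterations=100, seed=1)
        assert res  # records never entered: same call, same result
        again = go_enrichment(observed, mapping, iterations=100, seed=1)
        assert [(r.fold, r.p) for r in res] == [(r.fold, r.p) for r in again]


class TestReaders:
    def test_refgene_roundtrip_and_coordinates(self, tmp_path):
        genes = [
            GeneModel("A1", "c1", "+", 1_001, 5_000),
            GeneModel("B2", "c2", "-", 2_000, 9_000),
        ]
        path = tmp_path / "refGene.txt"
        write_refgene(genes, path)
        # txStart is written 0-based (UCSC dump convention), read back 1-based
        raw = path.read_text().splitlines()[0].split("\t")
        assert raw[4] == "1000"
        assert read_refgene(path) == genes

    def test_deduplicate_keeps_longest_transcript(self):
        txs = [
            GeneModel("A", "c", "+", 100, 200),
            GeneModel("A", "c", "+", 50, 500),
            GeneModel("B", "c", "-", 10, 20),
        ]
        dd = deduplicate(txs)
        assert dd == [GeneModel("A", "c", "+", 50, 500), GeneModel("B", "c", "-", 10, 20)]

    def test_gene_info_and_gene2go(self, tmp_path):
        mapping = make_mapping(3, 12)
        gi, g2g = tmp_path / "gene_info", tmp_path / "gene2go"
        write_gene_info(mapping, gi)
        write_gene2go(mapping, g2g)
        info = read_gene_info(gi)
        back = read_gene2go(g2g, info)
        assert back.gene_to_go == mapping.gene_to_go
        assert set(back.terms) == set(mapping.terms)

    def test_gene2go_non_process_rows_dropped(self, tmp_path):
        gi = tmp_path / "gene_info"
        gi.write_text("#h\n9606\t1\tSYM\t-\t-\n")
        g2g = tmp_path / "gene2go"
        g2g.write_text(
            "#h\n9606\t1\tGO:1\tIEA\t-\tx\t-\tProcess\n9606\t1\tGO:2\tIEA\t-\ty\t-\tFunction\n"
        )
        back = read_gene2go(g2g, read_gene_info(gi))
        assert back.gene_to_go == {"SYM": {"GO:1"}}


def test_synth_annotation_integrates_with_enrichment():
    """Planted fraction 1.0 puts every promoter of the category in the intervals."""
    spec = SynthSpec(
        total_length=200_000,
        seed=5,
        categories=[CategorySpec("GO:X", 20, 1.0), CategorySpec("GO:BG", 40, 0.0)],
    )
    intervals = [("synth1", 50_001, 80_000)]
    genes, mapping = synth_annotation(spec, intervals)
    proms = promoters(genes, {"synth1": 200_000})
    planted = [p for p in proms if "GO:X" in mapping.gene_to_go[p.symbol]]
    assert len(planted) == 20
    assert all(50_001 <= p.start and p.end <= 80_000 for p in planted)
    observed = genes_in_windows(proms, [("synth1", 50_001, 80_000)])
    assert {p.symbol for p in planted} <= observed
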