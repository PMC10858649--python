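import numpy as np
import pandas as pd
import pytest

from dinolnc.genome_io import PromoterRegion
from dinolnc.triplex import (
    InteractionGraph,
    TriplexParams,
    categorize_interactions,
    correlate_interaction_expression,
    deduplicate_features,
    find_all_hits,
    find_triplex_hits,
    group_target_genes,
    mask_low_complexity,
)

from _oracle_triplex import hit_tuple, oracle_hits

NO_FILTER = TriplexParams(repeat_filter=False)
# the canonical poly-T : poly-A triple helix has no guanine at all, so the
# guanine-rate rule must be lifted to observe it
POLY_A = TriplexParams(repeat_filter=False, min_guanine_rate=0.0)


def _prom(seq, gene_id="g1"):
    return PromoterRegion(gene_id, "chr1", "+", 0, len(seq), seq)


def _skewed_pair(rng, n_lnc=120, n_prom=400):
    """Composition-skewed sequences so triplex-compatible tracts occur."""
    lnc = "".join(rng.choice(list("ACGT"), size=n_lnc,
                             p=[0.15, 0.2, 0.25, 0.4]))
    prom = "".join(rng.choice(list("ACGT"), size=n_prom,
                              p=[0.4, 0.1, 0.35, 0.15]))
    return lnc, prom


class TestMasking:
    @pytest.mark.parametrize("seq,expected", [
        ("GGGGGGGG", "NNNNNNNN"),          # period 1, length 8
        ("GAGAGAG", "NNNNNNN"),            # period 2, total length 7
        ("GAGAGA", "GAGAGA"),              # below the length cutoff
        ("ACGTGGGGGGGACGT", "ACGTNNNNNNNACGT"),
    ])
    def test_tandem_repeat_masking(self, seq, expected):
        assert mask_low_complexity(seq) == expected

    def test_period_three_repeat(self):
        assert mask_low_complexity("GCAGCAGCA") == "NNNNNNNNN"


class TestSinglePairSearch:
    def test_poly_t_binds_poly_a_tract(self):
        hits = find_triplex_hits("L", "T" * 20, _prom("A" * 20), POLY_A)
        assert len(hits) == 1
        h = hits[0]
        assert (h.length, h.mismatches, h.motif, h.orientation) == (
            20, 0, "pyrimidine", "parallel")

    def test_one_central_mismatch_tolerated_two_rejected(self):
        prom1 = "A" * 9 + "C" + "A" * 10
        hits1 = find_triplex_hits("L", "T" * 20, _prom(prom1), POLY_A)
        assert any(h.length == 20 and h.mismatches == 1 for h in hits1)
        prom2 = "A" * 6 + "C" + "A" * 6 + "C" + "A" * 6
        hits2 = find_triplex_hits("L", "T" * 20, _prom(prom2), POLY_A)
        assert all(h.length < 20 or h.mismatches / h.length <= 0.05
                   for h in hits2)
        assert not any(h.length == 20 for h in hits2)

    def test_n_positions_never_match(self):
        # one N counts as a mismatch (1/20 = 5%, tolerated) ...
        hits = find_triplex_hits("L", "T" * 20, _prom("A" * 9 + "N" + "A" * 10),
                                 POLY_A)
        assert any(h.length == 20 and h.mismatches == 1 for h in hits)
        # ... two Ns exceed the error budget at minimum length
        hits2 = find_triplex_hits(
            "L", "T" * 20, _prom("A" * 6 + "N" + "A" * 6 + "N" + "A" * 6), POLY_A)
        assert not any(h.length >= 20 for h in hits2)

    def test_guanine_rate_constraint(self):
        # pure A tract has zero guanine; raising the threshold kills the hit
        params = TriplexParams(repeat_filter=False, min_guanine_rate=0.1)
        assert find_triplex_hits("L", "T" * 20, _prom("A" * 20), params) == []
        mixed = ("AAG" * 7)[:20]
        tfo = mixed.translate(str.maketrans("AG", "TC"))
        assert find_triplex_hits("L", tfo, _prom(mixed), params) != []

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_exhaustive_oracle_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        lnc, prom = _skewed_pair(rng)
        # embed a compatible tract so hit sets are frequently non-empty
        tract = "".join(rng.choice(["A", "G"], size=26))
        pos = int(rng.integers(0, len(prom) - 30))
        prom = prom[:pos] + tract + prom[pos + 26 :]
        tfo = tract.translate(str.maketrans("AG", "TC"))
        lpos = int(rng.integers(0, len(lnc) - 30))
        lnc = lnc[:lpos] + tfo + lnc[lpos + 26 :]
        for params in (NO_FILTER, TriplexParams()):
            got = [hit_tuple(h) for h in
                   find_triplex_hits("L", lnc, _prom(prom), params)]
            want = [hit_tuple(h) for h in
                    oracle_hits("L", lnc, _prom(prom), params)]
            assert got == want

    def test_reverse_complement_promoter_reflects_hits(self):
        rng = np.random.default_rng(99)
        lnc, prom = _skewed_pair(rng, 80, 200)
        tract = ("AAG" * 10)[:24]
        prom = prom[:50] + tract + prom[74:]
        lnc = lnc[:20] + tract.translate(str.maketrans("AG", "TC")) + lnc[44:]
        hits_fwd = find_triplex_hits("L", lnc, _prom(prom), NO_FILTER)
        from dinolnc._util import revcomp

        hits_rc = find_triplex_hits("L", lnc, _prom(revcomp(prom)), NO_FILTER)
        n = len(prom)
        reflected = {
            (h.tfo_offset, n - (h.tts_offset + h.length), h.length,
             h.mismatches, h.motif, h.orientation)
            for h in hits_rc
        }
        original = {
            (h.tfo_offset, h.tts_offset, h.length, h.mismatches, h.motif,
             h.orientation)
            for h in hits_fwd
        }
        assert original == reflected

    def test_empty_sequences_give_empty_result(self):
        assert find_triplex_hits("L", "", _prom("A" * 30), NO_FILTER) == []


class TestDeduplication:
    def _hit_at(self, lid, off):
        from dinolnc.triplex import TriplexHit

        return TriplexHit(lid, "g", off, 0, 20, 0, "pyrimidine", "parallel", "+")

    def test_unique_tfos_untouched(self):
        seqs = {f"l{i}": "ACGT" * 5 + "T" * i + "ACG" * 10 for i in range(3)}
        hits = [self._hit_at(f"l{i}", 0) for i in range(3)]
        assert deduplicate_features(hits, dc=5, lncrnas=seqs) == hits

    @pytest.mark.parametrize("n_loci,kept", [(5, True), (6, False)])
    def test_duplicate_cutoff_boundary(self, n_loci, kept):
        seqs = {f"l{i}": "T" * 20 + "ACG" * 10 for i in range(n_loci)}
        hits = [self._hit_at(f"l{i}", 0) for i in range(n_loci)]
        out = deduplicate_features(hits, dc=5, lncrnas=seqs)
        assert (len(out) == n_loci) is kept


class TestInteractionGraph:
    def _graph(self, edges):
        from dinolnc.triplex import TriplexHit

        hits = [TriplexHit(l, g, 0, 0, 20, 0, "pyrimidine", "parallel", "+")
                for l, g in edges]
        return InteractionGraph.from_hits(hits)

    def test_single_edge_is_one_to_one(self):
        cats, counts = categorize_interactions(self._graph([("L1", "g1")]))
        assert cats == {"L1": "one_to_one"}
        assert counts["one_to_one"] == 1

    def test_exclusive_multi_target_is_one_to_many(self):
        cats, _ = categorize_interactions(
            self._graph([("L1", "g1"), ("L1", "g2")]))
        assert cats["L1"] == "one_to_many"

    def test_shared_gene_makes_many_to_one(self):
        cats, _ = categorize_interactions(
            self._graph([("L1", "g1"), ("L2", "g1")]))
        assert cats == {"L1": "many_to_one", "L2": "many_to_one"}

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_definition_scan_and_partition(self, seed):
        rng = np.random.default_rng(seed)
        edges = {(f"L{rng.integers(8)}", f"g{rng.integers(8)}")
                 for _ in range(20)}
        graph = self._graph(sorted(edges))
        cats, counts = categorize_interactions(graph)
        assert counts.sum() == len(graph.lnc_to_genes)
        for l, genes in graph.lnc_to_genes.items():
            exclusive = all(len(graph.gene_to_lncs[g]) == 1 for g in genes)
            if len(genes) == 1:
                want = "one_to_one" if exclusive else "many_to_one"
            else:
                want = "one_to_many" if exclusive else "many_to_many"
            assert cats[l] == want


class TestExpressionCorrelation:
    def _setup(self, x, y):
        graph = InteractionGraph({"L": {"g"}}, {"g": {"L"}})
        de = pd.DataFrame({"status": ["up"]}, index=["g"])
        norm = pd.DataFrame([x, y], index=["L", "g"],
                            columns=[f"s{i}" for i in range(len(x))])
        return graph, de, norm

    def test_monotone_vectors_give_unit_rho(self):
        x = np.arange(10.0)
        graph, de, norm = self._setup(x, -x)
        out, summary = correlate_interaction_expression(graph, de, norm)
        assert out["spearman_rho"].iloc[0] == pytest.approx(-1.0)
        assert out["sign"].iloc[0] == "negative"
        assert summary["fraction_negative"] == 1.0
        out2, _ = correlate_interaction_expression(*self._setup(x, x * 3 + 1))
        assert out2["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_ties_match_direct_rank_formula(self):
        from scipy import stats as sps

        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 9.0, 9.0, 10.0])
        want = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        graph, de, norm = self._setup(x, y)
        out, _ = correlate_interaction_expression(graph, de, norm, rho_min=0.0,
                                                  p_max=1.0)
        assert out["spearman_rho"].iloc[0] == pytest.approx(want)

    def test_non_de_genes_and_weak_correlations_excluded(self):
        x = np.arange(8.0)
        graph, de, norm = self._setup(x, -x)
        de_ns = de.copy()
        de_ns["status"] = "ns"
        out, _ = correlate_interaction_expression(graph, de_ns, norm)
        assert out.empty


class TestTargetGroups:
    def test_planted_interaction_tiers_recovered_in_ascending_order(self):
        rng = np.random.default_rng(0)
        rows = []
        lncs = [f"L{i}" for i in range(25)]
        gi = 0
        for tier, n_int in [(6, 2), (6, 11), (6, 18)]:
            # genes in a block share the same partner set (block structure)
            partners = rng.choice(lncs, size=n_int, replace=False)
            for _ in range(tier):
                gene = f"g{gi}"
                gi += 1
                for l in partners:
                    rows.append((l, gene, float(-0.9 + rng.uniform(-0.05, 0.05)),
                                 0.001, "negative"))
        correlated = pd.DataFrame(
            rows, columns=["lncrna_id", "gene_id", "spearman_rho", "p", "sign"])
        groups = group_target_genes(correlated, n_groups=3)
        means = groups.groupby("group")["n_interactions"].mean()
        assert list(means.index) == [1, 2, 3]
        assert list(means.round().astype(int)) == [2, 11, 18]

    def test_identical_rows_form_one_group(self):
        rows = [(f"L{j}", f"g{i}", -0.9, 0.001, "negative")
                for i in range(4) for j in range(3)]
        correlated = pd.DataFrame(
            rows, columns=["lncrna_id", "gene_id", "spearman_rho", "p", "sign"])
        with pytest.warns(UserWarning):
            groups = group_target_genes(correlated, n_groups=5)
        assert groups["group"].nunique() <= 4

    def test_gene_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        rows = [(f"L{rng.integers(10)}", f"g{i}", float(rng.uniform(-1, -0.8)),
                 0.01, "negative")
                for i in range(9) for _ in range(rng.integers(2, 6))]
        correlated = pd.DataFrame(
            rows, columns=["lncrna_id", "gene_id", "spearman_rho", "p", "sign"]
        ).drop_duplicates(["lncrna_id", "gene_id"])
        g1 = group_target_genes(correlated)
        g2 = group_target_genes(correlated.iloc[::-1])
        merged = g1.merge(g2, on="gene_id", suffixes=("_a", "_b"))
        assert (merged["group_a"] == merged["group_b"]).all()


class TestEndToEnd:
    def test_planted_pairs_recovered_with_exact_coordinates(self, bundle,
                                                            cascade_result):
        from dinolnc.genome_io import extract_promoters

        lncrnas, _ = cascade_result
        proms = extract_promoters(bundle.annotation, bundle.genome)
        hits = find_all_hits({l.id: l.sequence for l in lncrnas}, proms)
        edges = {(h.lncrna_id, h.gene_id) for h in hits}
        for row in bundle.triplex_truth.itertuples():
            assert (row.lncrna_id, row.gene_id) in edges
            assert any(
                h.lncrna_id == row.lncrna_id and h.gene_id == row.gene_id
                and h.tfo_offset == row.tfo_offset
                and h.tts_offset == row.tts_offset and h.length == row.length
                for h in hits
            )

    def test_mismatch_rate_plants_respect_error_budget(self):
        from dinolnc.genome_io import extract_promoters
        from dinolnc.identify import run_cascade
        from dinolnc.simulate import (SimulationConfig, TriplexPlant,
                                      simulate_truth_bundle)

        cfg = SimulationConfig(
            seed=3,
            triplex_plants=tuple(TriplexPlant(r, "pyrimidine")
                                 for r in (0.0, 0.05, 0.10)),
        )
        b = simulate_truth_bundle(cfg)
        lncrnas, _ = run_cascade(b.alignments, b.annotation, b.counts)
        proms = extract_promoters(b.annotation, b.genome)
        hits = find_all_hits({l.id: l.sequence for l in lncrnas}, proms)
        edges = {(h.lncrna_id, h.gene_id) for h in hits}
        for row in b.triplex_truth.itertuples():
            found = (row.lncrna_id, row.gene_id) in edges
            assert found is (row.mismatch_rate <= 0.05)
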