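"""Expression statistics: probe collapse, Welch+BH differential expression,
hypergeometric over-representation (with exhaustive enumeration oracle)."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satflux as sf
from satflux.errors import ValidationError


def make_matrix(values, groups=("C", "C", "TB", "TB"), ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"ps{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return sf.ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples),
        groups=pd.Series(groups, index=samples),
    )


class TestCollapse:
    def annot(self, rows):
        return pd.DataFrame(rows, columns=["probeset_id", "gene_id", "three_prime_rank"])

    def test_single_probe_set_kept(self):
        m = make_matrix([[1, 2, 3, 4]], ids=["psA"])
        out = sf.collapse_to_gene(m, self.annot([("psA", "g1", 1)]))
        assert list(out.values.index) == ["g1"]

    def test_rank_one_row_retained(self):
        m = make_matrix([[1] * 4, [2] * 4, [3] * 4], ids=["a", "b", "c"])
        annot = self.annot([("a", "g1", 2), ("b", "g1", 1), ("c", "g1", 3)])
        out = sf.collapse_to_gene(m, annot)
        assert out.values.loc["g1"].tolist() == [2.0] * 4

    def test_generator_dataset_collapses_to_gene_count(self):
        spec = sf.ExpressionSimSpec(n_probesets=120, n_genes=100, seed=3)
        sim = sf.simulate_expression_dataset(spec)
        out = sf.collapse_to_gene(sim.matrix, sim.annotation)
        assert out.values.shape[0] == 100

    def test_duplicate_rank_one_rejected(self):
        m = make_matrix([[1] * 4, [2] * 4], ids=["a", "b"])
        with pytest.raises(ValidationError, match="duplicate rank-1"):
            sf.collapse_to_gene(m, self.annot([("a", "g1", 1), ("b", "g1", 1)]))

    def test_unannotated_probe_sets_dropped(self, caplog):
        m = make_matrix([[1] * 4, [2] * 4], ids=["a", "zz"])
        with caplog.at_level("INFO", logger="satflux.enrichment"):
            out = sf.collapse_to_gene(m, self.annot([("a", "g1", 1)]))
        assert list(out.values.index) == ["g1"]
        assert "dropped 1" in caplog.text


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        adj = sf.benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_monotone_capped_and_dominating(self, pvals):
        p = np.asarray(pvals)
        adj = sf.benjamini_hochberg(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestDifferentialExpression:
    def test_exact_twofold_shift_has_unit_log2fc(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(5, 0.05, size=(1, 4))
        vals = np.hstack([base, 2.0 * base])
        de = sf.differential_expression(
            make_matrix(vals, groups=("C",) * 4 + ("TB",) * 4)
        )
        assert de[0].log2_fold_change == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_gene_flagged_p1(self):
        vals = [[2.0, 2.0, 2.0, 2.0], [1.0, 1.1, 2.3, 2.1]]
        de = sf.differential_expression(make_matrix(vals))
        assert de[0].flagged and de[0].p_value == 1.0

    def test_planted_genes_recovered_with_power(self):
        spec = sf.ExpressionSimSpec(seed=21)
        sim = sf.simulate_expression_dataset(spec)
        collapsed = sf.collapse_to_gene(sim.matrix, sim.annotation)
        de = sf.differential_expression(collapsed)
        passing = {r.gene_id for r in de if r.passes}
        planted = set(sim.truth["planted_genes"])
        assert len(passing & planted) / len(planted) >= 0.9

    def test_global_null_fdr_control(self):
        """Mean fraction of adjusted-significant genes under the global null
        stays at or below the nominal 5% (20 seeds)."""
        fracs = []
        for seed in range(20):
            spec = sf.ExpressionSimSpec(
                n_probesets=2000, n_genes=2000, planted_fraction=0.0, seed=seed
            )
            sim = sf.simulate_expression_dataset(spec)
            collapsed = sf.collapse_to_gene(sim.matrix, sim.annotation)
            de = sf.differential_expression(collapsed)
            fracs.append(np.mean([r.fdr_adjusted_p <= 0.05 for r in de]))
        assert np.mean(fracs) <= 0.05


class TestUpDownPartition:
    def test_counts_match_generator_truth(self):
        spec = sf.ExpressionSimSpec(
            planted_fraction=0.05, planted_up_fraction=0.6, seed=4
        )
        sim = sf.simulate_expression_dataset(spec)
        collapsed = sf.collapse_to_gene(sim.matrix, sim.annotation)
        up, down = sf.up_down_partition(sf.differential_expression(collapsed))
        up_ids = {r.gene_id for r in up}
        down_ids = {r.gene_id for r in down}
        assert up_ids <= set(sim.truth["planted_up"])
        assert down_ids <= set(sim.truth["planted_down"])
        assert len(up_ids) >= 0.9 * len(sim.truth["planted_up"])
        assert len(down_ids) >= 0.9 * len(sim.truth["planted_down"])

    def test_all_positive_effects_leave_down_empty(self):
        spec = sf.ExpressionSimSpec(planted_up_fraction=1.0, seed=6)
        sim = sf.simulate_expression_dataset(spec)
        collapsed = sf.collapse_to_gene(sim.matrix, sim.annotation)
        _, down = sf.up_down_partition(sf.differential_expression(collapsed))
        assert down == []

    def test_zero_fold_change_never_passes(self):
        r = sf.DifferentialResult("g", 0.0, 0.0, 1e-9, 1e-9, passes=False)
        up, down = sf.up_down_partition([r])
        assert up == [] and down == []


def exact_hypergeom_tail(N, K, n, k):
    """Enumeration oracle: P(X >= k) as an exact rational tail sum."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return float(total)


class TestHypergeometricEnrichment:
    def run_single(self, N, K, n, k):
        universe = [f"g{i}" for i in range(N)]
        category = universe[:K]
        selected = category[:k] + universe[K : K + (n - k)]
        gene_map = {g: ["cat"] for g in category}
        res = sf.hypergeometric_enrichment(selected, gene_map, universe)
        assert len(res) == 1
        return res[0]

    def test_complete_overlap_probability(self):
        r = self.run_single(20, 5, 5, 5)
        assert r.p_value == pytest.approx(1.0 / math.comb(20, 5), rel=1e-9)
        assert r.p_value == pytest.approx(6.450e-5, rel=1e-3)

    def test_zero_overlap_tail_is_one(self):
        r = self.run_single(12, 4, 3, 0)
        assert r.p_value == pytest.approx(1.0, abs=1e-12)
        assert not r.kept  # overlap < 2

    def test_matches_enumeration_oracle_for_small_universes(self):
        for N in range(2, 16):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        r = self.run_single(N, K, n, k)
                        expected = exact_hypergeom_tail(N, K, n, k)
                        assert r.p_value == pytest.approx(expected, rel=1e-9), (N, K, n, k)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside the universe"):
            sf.hypergeometric_enrichment(["x"], {"g0": ["c"]}, ["g0"])

    def test_null_assignment_keeps_about_5pct(self):
        """Random selections and categories: the kept rate among categories
        with overlap >= 2 stays near (at or below ~) the nominal 5%."""
        rng = np.random.default_rng(0)
        kept = 0
        eligible = 0
        for _ in range(20):
            universe = [f"g{i}" for i in range(400)]
            selected = list(rng.choice(universe, 60, replace=False))
            gene_map = {}
            for c in range(30):
                for g in rng.choice(universe, 15, replace=False):
                    gene_map.setdefault(g, []).append(f"c{c}")
            for r in sf.hypergeometric_enrichment(selected, gene_map, universe):
                if r.overlap >= 2:
                    eligible += 1
                    kept += r.p_value <= 0.05
        assert eligible > 100
        assert kept / eligible <= 0.08
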