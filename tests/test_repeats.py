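import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import siterepeats as sr
from siterepeats.repeats import FALLBACK

from conftest import random_instance


def identifier_map(view, aln, table_entries=None):
    table = sr.RepeatTable(table_entries, aln.n_sites)
    return sr.compute_identifiers(view, aln, table), table


class TestTau:
    def test_bounds(self):
        assert sr.tau(1, 1, 16) == 1
        assert sr.tau(16, 16, 16) == 256

    def test_bijective_on_full_domain(self):
        seen = {sr.tau(a, b, 16) for a in range(1, 17) for b in range(1, 17)}
        assert seen == set(range(1, 257))


class TestCherryIdentifiers:
    def test_worked_example_cherry(self, toy):
        _, aln, _ = toy
        phi, maxid = sr.assign_identifiers_cherry(aln.row("t1"), aln.row("t2"))
        assert phi.tolist() == [1, 1, 2, 2, 1]
        assert maxid == 2

    def test_single_repeated_column(self):
        phi, maxid = sr.assign_identifiers_cherry([1] * 6, [4] * 6)
        assert phi.tolist() == [1] * 6 and maxid == 1

    def test_all_distinct_pairs(self):
        phi, maxid = sr.assign_identifiers_cherry([1, 2, 4, 8], [1, 2, 4, 8])
        assert phi.tolist() == [1, 2, 3, 4] and maxid == 4


class TestInnerIdentifiers:
    def test_worked_example_maps(self, toy):
        _, aln, view = toy
        idmap, _ = identifier_map(view, aln)
        w = view.find_clade(["t1", "t2"])
        v = view.find_clade(["t3", "t4"])
        assert idmap.phi(w).tolist() == [1, 1, 2, 2, 1] and idmap.maxid(w) == 2
        assert idmap.phi(v).tolist() == [1, 2, 3, 4, 2] and idmap.maxid(v) == 4
        # sites 2 and 5 (1-based) repeat at the root; everything else distinct
        assert idmap.phi(view.root).tolist() == [1, 2, 3, 4, 2]
        assert idmap.maxid(view.root) == 4

    def test_distinct_children_stay_distinct(self):
        table = sr.RepeatTable(None, 4)
        phi, maxid = sr.assign_identifiers_inner(
            [1, 2, 3, 4], 4, [1, 2, 3, 4], 4, table
        )
        assert phi.tolist() == [1, 2, 3, 4] and maxid == 4

    def test_table_bound_forces_fallback(self):
        table = sr.RepeatTable(1, 4)
        out = sr.assign_identifiers_inner([1, 1, 2, 2], 2, [1, 2, 1, 2], 2, table)
        assert out is FALLBACK

    def test_fallback_propagates_to_ancestors(self, toy):
        _, aln, view = toy
        idmap, _ = identifier_map(view, aln, table_entries=0)
        for u in view.postorder_inner():
            assert idmap.is_fallback(u)
            assert idmap.maxid(u) == aln.n_sites

    def test_table_reuse_across_nodes_is_safe(self):
        """Stale slots from a previous node are never trusted: two nodes
        with the same child-identifier pairs are assigned independently."""
        table = sr.RepeatTable(None, 3)
        phi1, m1 = sr.assign_identifiers_inner([1, 1, 2], 2, [1, 1, 2], 2, table)
        phi2, m2 = sr.assign_identifiers_inner([1, 2, 2], 2, [1, 2, 2], 2, table)
        assert phi1.tolist() == [1, 1, 2]
        assert phi2.tolist() == [1, 2, 2]


class TestIdentifierInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_partition_matches_brute_force(self, seed):
        """Soundness and completeness: equal identifiers at a node iff the
        columns restricted to that subtree's tips are identical."""
        view, aln = random_instance(seed)
        idmap, _ = identifier_map(view, aln)
        for u in view.postorder_inner():
            assert idmap.partition(u) == sr.brute_force_repeats(view, aln, u)

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_identifier_growth(self, seed):
        view, aln = random_instance(seed, min_sites=5)
        idmap, _ = identifier_map(view, aln)
        n = aln.n_sites
        rows = {t: i for i, t in enumerate(aln.taxa)}
        for u in view.postorder_inner():
            child_counts = []
            child_maxids = []
            for c in u.children:
                if c.is_tip:
                    child_counts.append(len(np.unique(aln.data[rows[c.label]])))
                    child_maxids.append(len(np.unique(aln.data[rows[c.label]])))
                else:
                    child_counts.append(idmap.maxid(c))
                    child_maxids.append(idmap.maxid(c))
            assert max(child_counts) <= idmap.maxid(u)
            assert idmap.maxid(u) <= min(n, child_maxids[0] * child_maxids[1])

    @pytest.mark.parametrize("seed", range(6))
    def test_root_maxid_equals_distinct_columns(self, seed):
        """At the root, repeat classes coincide with aliasing patterns."""
        view, aln = random_instance(seed, min_sites=5)
        idmap, _ = identifier_map(view, aln)
        distinct = np.unique(aln.data.T, axis=0).shape[0]
        assert idmap.maxid(view.root) == distinct

    def test_identifiers_dense_first_occurrence(self):
        view, aln = random_instance(99, min_sites=20)
        idmap, _ = identifier_map(view, aln)
        for u in view.postorder_inner():
            phi = idmap.phi(u)
            seen = []
            for x in phi:
                if x not in seen:
                    seen.append(x)
            assert seen == list(range(1, idmap.maxid(u) + 1))

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_partition_property_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(3, 8)), int(rng.integers(1, 20))
        data = rng.integers(1, 16, size=(m, n))
        aln = sr.Alignment([f"t{i+1}" for i in range(m)], data)
        tree = sr.random_tree(m, seed=seed)
        view = sr.root_at_terminal_edge(tree, "t1")
        idmap, _ = identifier_map(view, aln)
        for u in view.postorder_inner():
            assert idmap.partition(u) == sr.brute_force_repeats(view, aln, u)


class TestFullTraversal:
    def test_worked_example_counts(self, toy, gamma_model):
        _, aln, view = toy
        eng = sr.RepeatEngine(view, aln, gamma_model, table_entries=None)
        eng.run()
        assert eng.counters["clv_computations"] == 2 + 4 + 4 == 10
        assert eng.plain_clv_computations == 15

    @pytest.mark.parametrize("mode", ["srdt", "srct"])
    @pytest.mark.parametrize("table_entries", [0, 64, None])
    def test_likelihood_invariance(self, toy, gamma_model, mode, table_entries):
        """Repeats only skip duplicate work; the likelihood is unchanged for
        every mode and table bound."""
        _, aln, view = toy
        ref = sr.likelihood_rooted(view, aln, gamma_model)
        _, _, res = sr.repeats_full_traversal(
            view, aln, gamma_model, table_entries=table_entries, mode=mode
        )
        assert res.log_likelihood == pytest.approx(ref.log_likelihood, rel=1e-10)

    def test_clv_count_equals_maxid_sum(self):
        view, aln = random_instance(5, min_sites=10)
        model = sr.SubstModel.jc(alpha=1.0, n_categories=4)
        eng = sr.RepeatEngine(view, aln, model, table_entries=None)
        eng.run()
        assert eng.counters["clv_computations"] == sum(
            eng.idmap.maxid(u) for u in view.postorder_inner()
        )

    def test_weighted_patterns_honoured(self, gamma_model):
        view, aln = random_instance(17, min_sites=30)
        packed = sr.compress_patterns(aln)
        eng = sr.RepeatEngine(view, packed, gamma_model, table_entries=None)
        res = eng.run()
        ref = sr.likelihood_rooted(view, aln, gamma_model)
        assert res.log_likelihood == pytest.approx(ref.log_likelihood, rel=1e-10)

    def test_taxa_mismatch_rejected(self, toy, gamma_model):
        _, aln, view = toy
        other = sr.Alignment.from_sequences([("x1", "AC"), ("x2", "AC")])
        with pytest.raises(ValueError, match="lacks taxa"):
            sr.RepeatEngine(view, other, gamma_model)

    def test_compressed_store_expands_to_plain_clvs(self, toy, gamma_model):
        """LH entries indexed through phi reproduce the per-site CLVs."""
        from siterepeats.plf import compute_clvs

        _, aln, view = toy
        eng = sr.RepeatEngine(view, aln, gamma_model, table_entries=None)
        eng.run()
        plain = compute_clvs(view, aln, gamma_model)
        for u in view.postorder_inner():
            assert np.allclose(
                eng.store.site_clv(u, eng.idmap), plain.clv[u.index], rtol=1e-12
            )
            assert len(eng.store.lh[u.index]) == eng.idmap.maxid(u)


class TestModes:
    def test_srct_caches_identifiers(self, toy):
        _, aln, view = toy
        m1 = sr.SubstModel.jc(alpha=0.5, n_categories=4)
        eng = sr.RepeatEngine(view, aln, m1, table_entries=None, mode="srct")
        r1 = eng.run()
        phi_before = {i: rec.phi.copy() for i, rec in eng.idmap.entries.items()}
        eng.set_model(sr.SubstModel.jc(alpha=2.0, n_categories=4))
        r2 = eng.run()
        for i, rec in eng.idmap.entries.items():
            assert (rec.phi == phi_before[i]).all()
        assert r1.log_likelihood != r2.log_likelihood

    @pytest.mark.parametrize("seed", range(4))
    def test_srct_and_srdt_agree(self, seed, gamma_model):
        view, aln = random_instance(seed, min_sites=5)
        a = sr.RepeatEngine(view, aln, gamma_model, table_entries=None, mode="srdt")
        b = sr.RepeatEngine(view, aln, gamma_model, table_entries=None, mode="srct")
        ra, rb = a.run(), b.run()
        assert ra.log_likelihood == pytest.approx(rb.log_likelihood, rel=1e-12)
        for u in view.postorder_inner():
            assert (a.idmap.phi(u) == b.idmap.phi(u)).all()


class TestPartialUpdates:
    @pytest.fixture()
    def engine(self, gamma_model):
        tree, aln = sr.simulate_dataset(sr.SimConfig(n_taxa=20, n_sites=120, seed=4))
        view = sr.root_at_terminal_edge(tree, "t1")
        eng = sr.RepeatEngine(view, aln, gamma_model, table_entries=None)
        eng.run()
        return eng

    def test_empty_dirty_set_is_noop(self, engine):
        before = engine.result.log_likelihood
        res = engine.partial_update(sr.DirtySet())
        assert res.log_likelihood == before
        assert engine.counters["clv_computations"] == 0

    def test_all_dirty_equals_full_traversal(self, engine, gamma_model):
        full = engine.result.log_likelihood
        ds = sr.mark_dirty(engine.view, engine.view.postorder_inner())
        res = engine.partial_update(ds)
        assert res.log_likelihood == pytest.approx(full, rel=1e-12)

    def test_not_upward_closed_rejected(self, engine):
        deep = engine.view.postorder_inner()[0]
        with pytest.raises(ValueError, match="upward-closed"):
            engine.partial_update(sr.DirtySet(nodes=[deep]))

    @pytest.mark.parametrize("trial", range(5))
    def test_perturbed_branches_match_fresh_recompute(self, engine, gamma_model,
                                                      trial):
        rng = np.random.default_rng(trial)
        ds = sr.random_walk_dirty(engine.view, rng)
        for nd in ds.nodes:
            for c in nd.children:
                c.edge_length *= 1.0 + 0.2 * rng.random()
        res = engine.partial_update(ds)
        fresh = sr.RepeatEngine(engine.view, engine.alignment, gamma_model,
                                table_entries=None)
        ref = fresh.run()
        assert res.log_likelihood == pytest.approx(ref.log_likelihood, rel=1e-10)


class TestStatistics:
    def test_repeat_fraction_worked_example(self, toy):
        _, aln, view = toy
        assert sr.repeat_fraction(view, aln) == pytest.approx(100 * 5 / 15)

    def test_all_identical_columns(self):
        aln = sr.Alignment.from_sequences([("t1", "AAAA"), ("t2", "CCCC"),
                                           ("t3", "GGGG")])
        tree = sr.parse_newick("(t1:0.1,t2:0.1,t3:0.1);")
        frac = sr.repeat_fraction(tree, aln, root_taxon="t1")
        assert frac == pytest.approx(100 * (4 - 1) / 4)

    def test_all_distinct_columns_zero(self):
        aln = sr.Alignment.from_sequences([("t1", "ACGT"), ("t2", "ACGT"),
                                           ("t3", "ACGT")])
        tree = sr.parse_newick("(t1:0.1,t2:0.1,t3:0.1);")
        assert sr.repeat_fraction(tree, aln, root_taxon="t1") == 0.0

    def test_memory_estimate_formula(self, toy):
        _, aln, view = toy
        idmap, table = identifier_map(view, aln)
        rep = sr.memory_estimate(4, 5, idmap, n_categories=4, table=table)
        assert rep["standard_clv_bytes"] == 8 * 4 * 4 * (4 - 2) * 5 == 1280
        assert rep["compressed_clv_bytes"] <= rep["view_clv_bytes"]
        assert rep["clv_values_per_identifier"] == 16
        assert rep["compressed_clv_bytes"] == 8 * 4 * 4 * (2 + 4 + 4)

    @pytest.mark.parametrize("seed", range(4))
    def test_compression_never_exceeds_uncompressed(self, seed):
        view, aln = random_instance(seed, min_sites=5)
        idmap, _ = identifier_map(view, aln)
        rep = sr.memory_estimate(view.n_taxa, aln.n_sites, idmap)
        assert rep["compressed_clv_bytes"] <= rep["view_clv_bytes"]

    def test_table_size_conversions(self):
        assert sr.table_entries_for_mb(200) == 50_000_000
        assert sr.DEFAULT_TABLE_ENTRIES == 50_000_000
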