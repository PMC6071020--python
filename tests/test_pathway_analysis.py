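import numpy as np
import pytest

from dynsig import (Pathway, RunConfig, adjust_qvalues, dep_score,
                    random_pathway_pvalue, run_dynsig, simulate_dataset)
from dynsig.synthetic_data import SimulationConfig


class TestPathway:
    def test_self_links_and_duplicates_removed(self):
        pw = Pathway("p", [("a", "b"), ("a", "a"), ("a", "b"), ("b", "c")])
        assert pw.links == [("a", "b"), ("b", "c")]
        assert pw.L == 2 and pw.genes == {"a", "b", "c"}

    def test_empty_after_cleaning_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            Pathway("p", [("a", "a")])


class TestDepScore:
    def test_mean_of_link_accuracies(self):
        assert dep_score([0.8, 0.6, 1.0]) == pytest.approx(0.8)
        assert dep_score([0.5, 0.5, 0.5]) == 0.5
        assert dep_score([0.73]) == 0.73

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dep_score([])


class TestAdjustQvalues:
    def test_step_up(self):
        assert np.allclose(adjust_qvalues([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_degenerate(self):
        assert np.allclose(adjust_qvalues([1.0, 1.0]), [1.0, 1.0])
        assert np.allclose(adjust_qvalues([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_qvalues([0.5, 1.5])


class TestRandomPathwayPvalue:
    def test_maximal_dep_has_zero_pvalue(self, separable_states):
        pw = Pathway("sep", [("g1", "g2")])
        p = random_pathway_pvalue(pw, separable_states, Z=50, rng=0)
        assert p == 0.0  # nothing strictly exceeds DEP = 1

    def test_single_draw_bounds(self, separable_states):
        p = random_pathway_pvalue(pw := Pathway("sep", [("g1", "g2")]),
                                  separable_states, Z=1, rng=0)
        assert p in (0.0, 1.0)
        p_s = random_pathway_pvalue(pw, separable_states, Z=1, rng=0,
                                    smoothed=True)
        assert p_s in (0.5, 1.0)

    def test_absent_genes_rejected(self, separable_states):
        with pytest.raises(ValueError, match="no link present"):
            random_pathway_pvalue(Pathway("x", [("nope", "nada")]),
                                  separable_states, Z=10, rng=0)

    @pytest.mark.parametrize("gene_pool,shuffle", [
        ("pathway", True), ("pathway", False), ("genome", True)])
    def test_null_variants_run_and_bound(self, gene_pool, shuffle):
        ds = simulate_dataset(SimulationConfig(n_pathways=4, n_per_class=12,
                                               r=0.6, rho=0.5, seed=2))
        p = random_pathway_pvalue(ds.pathways[0], ds.states, Z=40, rng=1,
                                  gene_pool=gene_pool, shuffle_labels=shuffle)
        assert 0.0 <= p <= 1.0


class TestRunPipeline:
    def test_separable_dep_pathway_ranks_first(self):
        """With r = 1 and noise-free emissions, the DEP pathway is
        perfectly class-separated and gets the minimum p-value."""
        cfg = SimulationConfig(n_pathways=2, n_per_class=10, r=1.0, rho=1.0,
                               normal_sd=0.0, seed=4)
        ds = simulate_dataset(cfg)
        res = run_dynsig(ds.expression, ds.pathways,
                         RunConfig(discretizer="fixed", Z=100, seed=1))
        dep_name = ds.pathways[int(np.where(ds.dep_truth)[0][0])].name
        assert res[0].name == dep_name
        assert res[0].p == min(r.p for r in res)
        assert res[0].dep == 1.0

    def test_presence_filter_drops_sparse_pathways(self, separable_states):
        pws = [Pathway("in", [("g1", "g2"), ("g2", "g1")]),
               Pathway("one_link", [("g1", "g2"), ("g2", "zzz")]),
               Pathway("out", [("x", "y")])]
        with pytest.warns(UserWarning):
            res = run_dynsig(separable_states, pws, RunConfig(Z=20, seed=0))
        assert [r.name for r in res] == ["in"]

    def test_dep_equals_mean_of_link_scores_and_q_assigned(self):
        ds = simulate_dataset(SimulationConfig(n_pathways=6, n_per_class=10,
                                               r=0.7, rho=0.5, seed=8))
        res = run_dynsig(ds.expression, ds.pathways,
                         RunConfig(discretizer="fixed", Z=50, seed=2))
        assert len(res) == 6
        for r in res:
            assert r.dep == pytest.approx(r.link_scores.d.mean())
            assert 0 <= r.dep <= 1 and 0 <= r.p <= 1 and 0 <= r.q <= 1
        assert [r.p for r in res] == sorted(r.p for r in res)

    def test_bit_reproducible_under_fixed_seed(self):
        ds = simulate_dataset(SimulationConfig(n_pathways=4, n_per_class=10,
                                               r=0.7, rho=0.5, seed=9))
        cfg = RunConfig(discretizer="fixed", Z=50, B=20, seed=5)
        r1 = run_dynsig(ds.expression, ds.pathways, cfg)
        r2 = run_dynsig(ds.expression, ds.pathways, cfg)
        for a, b in zip(r1, r2):
            assert (a.name, a.dep, a.p, a.q) == (b.name, b.dep, b.p, b.q)
            assert np.array_equal(a.link_scores.p_link, b.link_scores.p_link)

    def test_pvalues_invariant_to_pathway_order(self):
        ds = simulate_dataset(SimulationConfig(n_pathways=5, n_per_class=10,
                                               r=0.7, rho=0.5, seed=10))
        cfg = RunConfig(discretizer="fixed", Z=50, seed=3)
        fwd = run_dynsig(ds.expression, ds.pathways, cfg)
        rev = run_dynsig(ds.expression, ds.pathways[::-1], cfg)
        assert {r.name: r.p for r in fwd} == {r.name: r.p for r in rev}

    def test_no_surviving_pathway_warns_and_returns_empty(self, separable_states):
        with pytest.warns(UserWarning, match="no pathway survived"):
            res = run_dynsig(separable_states, [Pathway("out", [("x", "y")])],
                             RunConfig(Z=10, seed=0))
        assert res == []

    def test_per_link_pvalues_attached_when_B_positive(self, separable_states):
        pw = Pathway("in", [("g1", "g2"), ("g2", "g1")])
        res = run_dynsig(separable_states, [pw], RunConfig(Z=10, B=25, seed=0))
        assert res[0].link_scores.p_link.shape == (2,)
        assert (res[0].link_scores.p_link == 0).all()  # separable links
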