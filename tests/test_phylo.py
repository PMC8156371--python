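"""Faith's PD, phylogenetic endemism and SES-standardized PD."""

import dendropy
import numpy as np
import pytest

from spatdiv.datamodel import OccurrenceMatrix, Phylogeny
from spatdiv.errors import AlignmentError, ConfigError
from spatdiv.experiments import naive_pd_pe, star_tree_check
from spatdiv.phylo import (
    branch_range_table,
    classify_pdses,
    faith_pd,
    pd_ses,
    phylogenetic_endemism,
    ses_surface,
)
from spatdiv.synth import ScenarioConfig, simulate_ranges, simulate_tree
from spatdiv.datamodel import MetricSurface


def _occ(records):
    return OccurrenceMatrix.from_records(records)


class TestPDPE:
    def test_pd_hand_enumeration(self, toy_tree):
        occ = _occ(
            [("A", "ab"), ("B", "ab"), ("C", "c"),
             ("A", "all"), ("B", "all"), ("C", "all")]
        )
        pd_surface = faith_pd(occ, toy_tree)
        assert pd_surface.values["ab"] == pytest.approx(3.0)
        assert pd_surface.values["c"] == pytest.approx(2.0)   # root path only
        assert pd_surface.values["all"] == pytest.approx(5.0)  # whole tree

    def test_pe_hand_computation(self, toy_occ, toy_tree):
        pe = phylogenetic_endemism(toy_occ, toy_tree)
        assert pe.values["c1"] == pytest.approx(2.0)  # 1/1 + 1/2 + 1/2
        assert pe.values["c2"] == pytest.approx(3.0)  # 1/2 + 1/2 + 2/1
        pd_surface = faith_pd(toy_occ, toy_tree)
        for c in pe.defined_cells():
            assert pe.values[c] <= pd_surface.values[c] + 1e-12

    def test_empty_cell_undefined(self, toy_tree):
        occ = OccurrenceMatrix(
            ["A", "B", "C"], ["c1", "c2"],
            np.array([[True, True, True], [False, False, False]]),
        )
        assert "c2" not in faith_pd(occ, toy_tree)
        assert "c2" not in phylogenetic_endemism(occ, toy_tree)

    def test_unpruned_tree_rejected(self, toy_occ):
        big = Phylogeny(dendropy.Tree.get(
            data="(((A:1,B:1):1,C:2):1,D:3);", schema="newick"
        ))
        with pytest.raises(AlignmentError):
            faith_pd(toy_occ, big)

    def test_cell_confined_clades_make_pe_equal_pd(self):
        # whole clades confined to single cells: every branch range is 1
        occ = _occ([("A", "c1"), ("B", "c1"), ("C", "c3")])
        tree = Phylogeny(dendropy.Tree.get(
            data="((A:1,B:2):1,C:3);", schema="newick"
        ))
        pe = phylogenetic_endemism(occ, tree)
        pd_surface = faith_pd(occ, tree)
        assert pe.values == pytest.approx(pd_surface.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_pe_conservation_identity(self, seed):
        config = ScenarioConfig(
            seed=seed + 100, n_taxa=40, grid_rows=6, grid_cols=6,
            logseries_p=0.9, cohesion=0.4,
        )
        occ, _ = simulate_ranges(config)
        tree = simulate_tree(config)
        pe = phylogenetic_endemism(occ, tree)
        assert pe.defined_values().sum() == pytest.approx(
            tree.total_length(), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_branch_enumeration(self, seed):
        config = ScenarioConfig(
            seed=seed + 50, n_taxa=25, grid_rows=5, grid_cols=5,
            logseries_p=0.9, cohesion=0.3,
        )
        occ, _ = simulate_ranges(config)
        tree = simulate_tree(config)
        pd_ref, pe_ref = naive_pd_pe(occ, tree)
        pd_fast = faith_pd(occ, tree)
        pe_fast = phylogenetic_endemism(occ, tree)
        for c in pd_fast.defined_cells():
            assert pd_fast.values[c] == pytest.approx(pd_ref[c], abs=1e-9)
            assert pe_fast.values[c] == pytest.approx(pe_ref[c], abs=1e-9)

    def test_star_tree_collapses_to_taxonomic_metrics(self):
        result = star_tree_check(n_instances=5, seed=3)
        assert result["max_pe_we_diff"] <= 1e-12
        assert result["max_pd_sr_diff"] <= 1e-12


class TestBranchRanges:
    def test_branch_ranges_toy(self, toy_occ, toy_tree):
        table = branch_range_table(toy_occ, toy_tree)
        assert sorted(table["range"]) == [1, 1, 2, 2]
        assert (table["range"] >= 1).all()
        assert (table["range"] <= toy_occ.n_cells).all()

    def test_parent_range_dominates_children(self, small_dataset):
        occ, tree = small_dataset.occ, small_dataset.tree
        # recompute per-node ranges independently via tip sets
        cell_taxa = [set(occ.taxa_of_cell(c)) for c in occ.cells]
        for node in tree.tree.preorder_node_iter():
            if node.is_leaf() or node.edge.length is None:
                continue
            tips = {l.taxon.label for l in node.leaf_iter()}
            r_parent = sum(1 for ct in cell_taxa if ct & tips)
            for child in node.child_nodes():
                ctips = {l.taxon.label for l in child.leaf_iter()}
                r_child = sum(1 for ct in cell_taxa if ct & ctips)
                assert r_parent >= r_child


class TestPDSES:
    def test_distant_lineages_score_higher_than_sisters(self):
        tree = Phylogeny(dendropy.Tree.get(
            data="((A:1,B:1):10,(C:1,D:1):10);", schema="newick"
        ))
        occ = _occ(
            [("A", "mixed"), ("C", "mixed"), ("A", "sisters"), ("B", "sisters"),
             ("B", "bg"), ("D", "bg")]
        )
        ens = pd_ses(occ, tree, n_perm=199, seed=8)
        assert ens.ses["mixed"] > ens.ses["sisters"]

    def test_full_cell_has_undefined_ses(self, toy_tree):
        occ = _occ([("A", "full"), ("B", "full"), ("C", "full")])
        ens = pd_ses(occ, toy_tree, n_perm=29, seed=2)
        assert "full" not in ens.ses          # null sd = 0, flagged
        assert ens.observed["full"] == pytest.approx(5.0)

    def test_null_data_give_centered_ses(self):
        result_seed = 4
        config = ScenarioConfig(seed=result_seed, n_taxa=60)
        tree = simulate_tree(config)
        rng = np.random.default_rng(result_seed)
        n_cells, n_taxa = 400, 60
        X = np.zeros((n_cells, n_taxa), dtype=bool)
        for i, k in enumerate(rng.integers(2, 25, size=n_cells)):
            X[i, rng.choice(n_taxa, size=int(k), replace=False)] = True
        occ = OccurrenceMatrix(
            [f"t{i + 1:04d}" for i in range(n_taxa)],
            [f"c{i:04d}" for i in range(n_cells)], X,
        )
        ens = pd_ses(occ, tree, n_perm=199, seed=9)
        ses = np.array(list(ens.ses.values()))
        assert abs(ses.mean()) < 0.2
        assert 0.85 < ses.std(ddof=1) < 1.15

    def test_tip_label_shuffle_alternative(self, small_dataset):
        occ, tree = small_dataset.occ, small_dataset.tree
        ens = pd_ses(occ, tree, n_perm=29, null_model="tip_label_shuffle",
                     seed=6)
        assert ens.algorithm == "tip_label_shuffle"
        assert len(ens.ses) > 0

    def test_config_errors(self, toy_occ, toy_tree):
        with pytest.raises(ConfigError):
            pd_ses(toy_occ, toy_tree, n_perm=1, seed=1)
        with pytest.raises(ConfigError):
            pd_ses(toy_occ, toy_tree, seed=None)
        with pytest.raises(ConfigError):
            pd_ses(toy_occ, toy_tree, null_model="bogus", seed=1)


class TestClassification:
    def test_thresholds_are_boundary_inclusive(self):
        surface = MetricSurface(
            "PD_SES", ["over", "under", "mid", "gap"],
            {"over": 1.96, "under": -1.96, "mid": 0.0},
        )
        classes = classify_pdses(surface)
        assert classes == {
            "over": "overdispersed",
            "under": "clustered",
            "mid": "nonsignificant",
            "gap": "undefined",
        }

    def test_ses_surface_extraction(self, small_dataset):
        occ, tree = small_dataset.occ, small_dataset.tree
        ens = pd_ses(occ, tree, n_perm=29, seed=3)
        surface = ses_surface(ens)
        assert surface.name == "PD_SES"
        assert set(surface.values) == set(ens.ses)
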