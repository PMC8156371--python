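"""Richness, weighted endemism and the CWE permutation null."""

import numpy as np
import pytest

from spatdiv.datamodel import FLORISTIC_REGIONS, OccurrenceMatrix
from spatdiv.errors import ConfigError, ValidationError
from spatdiv.synth import ScenarioConfig, simulate_ranges
from spatdiv.taxonomic import (
    _to_sets,
    corrected_weighted_endemism,
    curveball_trades,
    cwe_significance,
    region_occupancy,
    species_richness,
    weighted_endemism,
)


def _random_occ(rng, n_taxa=30, n_cells=20, density=0.2):
    X = rng.random((n_cells, n_taxa)) < density
    X[rng.integers(n_cells, size=n_taxa), np.arange(n_taxa)] = True
    return OccurrenceMatrix(
        [f"t{i:03d}" for i in range(n_taxa)],
        [f"c{i:03d}" for i in range(n_cells)],
        X,
    )


class TestSurfaces:
    def test_toy_hand_values(self, toy_occ):
        sr = species_richness(toy_occ)
        assert sr.values == {"c1": 2.0, "c2": 2.0}
        we = weighted_endemism(toy_occ)
        assert we.values["c1"] == pytest.approx(1.5)   # 1/1 + 1/2
        assert we.values["c2"] == pytest.approx(1.5)
        cwe = corrected_weighted_endemism(toy_occ)
        assert cwe.values["c1"] == pytest.approx(0.75)

    def test_empty_cell_sr_zero_cwe_undefined(self):
        occ = OccurrenceMatrix(
            ["A"], ["c1", "c2"], np.array([[True], [False]])
        )
        assert species_richness(occ).values["c2"] == 0.0
        cwe = corrected_weighted_endemism(occ)
        assert "c2" not in cwe
        assert cwe.undefined_cells() == ["c2"]

    def test_all_single_cell_endemics_reach_upper_bound(self):
        occ = OccurrenceMatrix(
            ["A", "B"], ["c1", "c2"],
            np.array([[True, False], [False, True]]),
        )
        cwe = corrected_weighted_endemism(occ)
        assert all(v == 1.0 for v in cwe.values.values())
        we = weighted_endemism(occ)
        assert we.values == species_richness(occ).values

    def test_maximally_widespread_taxa_reach_lower_limit(self):
        occ = OccurrenceMatrix(
            ["A", "B"], ["c1", "c2", "c3"], np.ones((3, 2), dtype=bool)
        )
        cwe = corrected_weighted_endemism(occ)
        assert all(v == pytest.approx(1 / 3) for v in cwe.values.values())

    def test_richness_totals_presences(self, small_dataset):
        occ = small_dataset.occ
        sr = species_richness(occ)
        assert sum(sr.values.values()) == occ.n_presences

    @pytest.mark.parametrize("seed", range(6))
    def test_we_conservation_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        occ = _random_occ(rng)
        we = weighted_endemism(occ)
        sr = species_richness(occ)
        assert sum(we.values.values()) == pytest.approx(occ.n_taxa, abs=1e-9)
        for c in occ.cells:
            assert we.values[c] <= sr.values[c] + 1e-12
        cwe = corrected_weighted_endemism(occ)
        for v in cwe.values.values():
            assert 0 < v <= 1 + 1e-12

    def test_adding_presence_never_decreases_sr_or_we(self):
        rng = np.random.default_rng(7)
        occ = _random_occ(rng)
        we0 = weighted_endemism(occ).values
        sr0 = species_richness(occ).values
        absent = np.argwhere(~occ.presence)
        ci, ti = absent[rng.integers(len(absent))]
        X = occ.presence.copy()
        X[ci, ti] = True
        occ2 = OccurrenceMatrix(occ.taxa, occ.cells, X)
        cell = occ.cells[ci]
        assert species_richness(occ2).values[cell] == sr0[cell] + 1
        assert weighted_endemism(occ2).values[cell] >= we0[cell]


class TestCurveballNull:
    def test_trades_preserve_both_margins(self):
        rng = np.random.default_rng(3)
        occ = _random_occ(rng, n_taxa=40, n_cells=25)
        rows = _to_sets(occ)
        curveball_trades(rows, 5000, np.random.default_rng(11))
        assert [len(s) for s in rows] == list(occ.range_sizes())
        col = np.zeros(occ.n_cells, dtype=int)
        for s in rows:
            for c in s:
                col[c] += 1
        assert np.array_equal(col, occ.cell_richness())

    def test_margin_check_on_every_replicate(self):
        rng = np.random.default_rng(5)
        occ = _random_occ(rng, n_taxa=15, n_cells=10)
        cwe_significance(occ, n_perm=20, seed=1, check_margins=True)

    def test_identical_seed_identical_ensemble(self):
        occ = _random_occ(np.random.default_rng(9))
        a = cwe_significance(occ, n_perm=49, seed=123)
        b = cwe_significance(occ, n_perm=49, seed=123)
        assert a.p_value == b.p_value and a.null_mean == b.null_mean
        c = cwe_significance(occ, n_perm=49, seed=124)
        assert c.p_value != a.p_value

    def test_permutation_p_floor(self):
        # an extreme concentration of endemics: p hits the two-tailed floor
        cells = [f"c{i:02d}" for i in range(30)]
        records = [(f"e{i}", "c00") for i in range(10)]
        records += [
            (f"w{j}", cells[(3 * j + i) % 30])
            for j in range(10) for i in range(8)
        ]
        occ = OccurrenceMatrix.from_records(records)
        ens = cwe_significance(occ, n_perm=99, seed=5)
        assert min(ens.p_value.values()) >= 1 / 100
        assert ens.p_value["c00"] == pytest.approx(2 / 100)  # two-tailed floor
        assert ens.significance()["c00"] == "high"

    def test_config_errors(self, toy_occ):
        with pytest.raises(ConfigError):
            cwe_significance(toy_occ, n_perm=0, seed=1)
        with pytest.raises(ConfigError):
            cwe_significance(toy_occ, seed=None)
        with pytest.raises(ConfigError):
            cwe_significance(toy_occ, algorithm="swap", seed=1)

    def test_tip_shuffle_alternative(self):
        occ = _random_occ(np.random.default_rng(2))
        ens = cwe_significance(occ, n_perm=49, algorithm="tip_shuffle", seed=3)
        assert ens.algorithm == "tip_shuffle"
        assert all(1 / 50 <= p <= 1 for p in ens.p_value.values())

    def test_planted_center_detected(self):
        config = ScenarioConfig(
            seed=77, n_taxa=60, grid_rows=8, grid_cols=8,
            endemic_fraction=0.0, logseries_p=0.9, cohesion=0.5,
            background_range_min=3,
        )
        from spatdiv.synth import PlantedCenter

        config.planted = PlantedCenter(block=[(4, 4)], n_endemics=12)
        occ, truth = simulate_ranges(config)
        ens = cwe_significance(occ, n_perm=199, seed=11)
        sig = ens.significance()
        assert all(sig[c] == "high" for c in truth["planted_cells"])


class TestRegionOccupancy:
    def test_single_region_proportion(self):
        table, summary = region_occupancy(
            {"A": {"Pe"}, "B": {"Pe", "StE"}, "C": {"KK"}},
            FLORISTIC_REGIONS,
            endemic_taxa={"A", "C"},
        )
        assert summary["single_region_proportion"] == pytest.approx(2 / 3)
        assert summary["endemic_single_region_proportion"] == pytest.approx(1.0)
        pe = table.set_index("region").loc["Pe"]
        assert pe["prop_taxa"] == pytest.approx(2 / 3)

    def test_ubiquitous_taxa_have_no_single_region(self):
        taxa = {t: set(FLORISTIC_REGIONS) for t in "ABC"}
        _, summary = region_occupancy(taxa, FLORISTIC_REGIONS)
        assert summary["single_region_proportion"] == 0.0

    def test_unknown_region_label_rejected(self):
        with pytest.raises(ValidationError):
            region_occupancy({"A": {"XX"}}, FLORISTIC_REGIONS)

    def test_recovers_generator_mixing(self, small_dataset):
        occ, regions = small_dataset.occ, small_dataset.regions
        taxon_regions = {
            t: {regions.region_of(c) for c in occ.cells_of_taxon(t)}
            for t in occ.taxa
        }
        _, summary = region_occupancy(taxon_regions, FLORISTIC_REGIONS)
        # most synthetic taxa are narrow-ranged, hence single-region
        assert summary["single_region_proportion"] > 0.4
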