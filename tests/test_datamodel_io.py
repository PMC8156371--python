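"""Readers, writers, validation and input alignment."""

import numpy as np
import pytest

from spatdiv.datamodel import MetricSurface, OccurrenceMatrix, TraitTable
from spatdiv.errors import (
    AlignmentError,
    EmptyInputError,
    FormatError,
    ValidationError,
)
from spatdiv.io import (
    align_inputs,
    eea_cell_polygon,
    eea_grid_geometry,
    read_occurrences,
    read_surface,
    read_tree,
    write_surface,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadOccurrences:
    def test_transcribes_records(self, tmp_path):
        p = _write(tmp_path, "occ.csv", "taxon,cell\nA,c1\nB,c1\nB,c2\nC,c2\n")
        occ = read_occurrences(p)
        assert (occ.n_taxa, occ.n_cells, occ.n_presences) == (3, 2, 4)
        assert occ.taxa == ["A", "B", "C"]      # lexicographic
        assert occ.cells == ["c1", "c2"]

    def test_duplicates_collapse_to_one_presence(self, tmp_path, caplog):
        p = _write(tmp_path, "occ.csv", "taxon,cell\nA,c1\nA,c1\nB,c1\nB,c2\n")
        with caplog.at_level("WARNING", logger="spatdiv"):
            occ = read_occurrences(p)
        assert occ.n_presences == 3
        assert "duplicate" in caplog.text

    def test_missing_column_named_in_error(self, tmp_path):
        p = _write(tmp_path, "occ.csv", "taxon,site\nA,c1\n")
        with pytest.raises(FormatError, match="cell"):
            read_occurrences(p)

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "occ.csv", "")
        with pytest.raises(EmptyInputError):
            read_occurrences(p)

    def test_empty_identifier_rejected(self, tmp_path):
        p = _write(tmp_path, "occ.csv", "taxon,cell\nA,c1\n,c2\n")
        with pytest.raises(FormatError):
            read_occurrences(p)

    def test_generator_roundtrip_preserves_shape(self, tmp_path, small_dataset):
        occ = small_dataset.occ
        occ.to_long_frame().to_csv(tmp_path / "occ.csv", index=False)
        back = read_occurrences(tmp_path / "occ.csv")
        assert back.taxa == occ.taxa
        assert (back.range_sizes() >= 1).all()
        # unoccupied grid cells are not present in the long format
        occupied = [c for c, k in zip(occ.cells, occ.cell_richness()) if k > 0]
        assert back.cells == occupied


class TestReadTree:
    def test_tip_count_and_total_length(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A:1,B:1):1,C:2);")
        phy = read_tree(p)
        assert phy.n_tips == 3
        assert phy.total_length() == pytest.approx(5.0)

    def test_missing_branch_lengths_rejected(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A,B),C);")
        with pytest.raises(ValidationError, match="branch lengths"):
            read_tree(p)

    def test_negative_branch_length_rejected(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A:1,B:-0.5):1,C:2);")
        with pytest.raises(ValidationError, match="negative"):
            read_tree(p)

    def test_unparseable_newick_is_format_error(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((A:1,B:1:1,C);;(")
        with pytest.raises(FormatError):
            read_tree(p)


class TestAlignInputs:
    def test_prunes_extra_tips_and_restricts_traits(self, tmp_path):
        occ = OccurrenceMatrix.from_records(
            [("A", "c1"), ("B", "c1"), ("C", "c2")]
        )
        tree = read_tree(_write(tmp_path, "t.nwk", "((A:1,B:1):1,(C:1,D:1):1);"))
        traits = TraitTable.__new__(TraitTable)
        import pandas as pd

        traits = TraitTable(pd.DataFrame(
            {"taxon": ["A", "B", "Z"], "trait": ["life_form"] * 3,
             "value": ["H", "Ch", "H"]}
        ))
        _, pruned, restricted, report = align_inputs(occ, tree, traits)
        assert sorted(pruned.tip_labels()) == ["A", "B", "C"]
        assert report["dropped_tips"] == ["D"]
        assert report["orphan_trait_taxa"] == ["Z"]
        assert report["trait_coverage"] == (2, 3)

    def test_disjoint_tip_sets_fatal(self, tmp_path):
        occ = OccurrenceMatrix.from_records([("A", "c1")])
        tree = read_tree(_write(tmp_path, "t.nwk", "(X:1,Y:1);"))
        with pytest.raises(AlignmentError):
            align_inputs(occ, tree)

    def test_idempotent(self, tmp_path):
        occ = OccurrenceMatrix.from_records([("A", "c1"), ("B", "c2")])
        tree = read_tree(_write(tmp_path, "t.nwk", "((A:1,B:1):1,C:2);"))
        _, once, _, _ = align_inputs(occ, tree)
        _, twice, _, _ = align_inputs(occ, once)
        assert once.as_newick() == twice.as_newick()


class TestSurfaceRoundTrip:
    def test_bit_exact_roundtrip_with_undefined(self, tmp_path):
        surface = MetricSurface(
            "CWE", ["c1", "c2", "c3"],
            {"c1": 0.1 + 0.2, "c2": 1.0 / 3.0},   # awkward floats on purpose
        )
        path = tmp_path / "s.csv"
        write_surface(surface, path)
        text = path.read_text()
        assert "c3,CWE,\n" in text         # undefined is empty, never "0"
        back = read_surface(path)
        assert back.name == "CWE"
        assert back.cells == surface.cells
        assert back.values == surface.values   # exact equality

    def test_large_synthetic_surface_roundtrip(self, tmp_path, small_dataset):
        from spatdiv.taxonomic import corrected_weighted_endemism

        surface = corrected_weighted_endemism(small_dataset.occ)
        path = tmp_path / "cwe.csv"
        write_surface(surface, path)
        back = read_surface(path)
        assert back.values == surface.values
        assert back.undefined_cells() == surface.undefined_cells()

    def test_empty_surface_rejected(self, tmp_path):
        with pytest.raises(EmptyInputError):
            write_surface(MetricSurface("SR", [], {}), tmp_path / "x.csv")

    def test_value_outside_domain_rejected(self):
        with pytest.raises(ValidationError):
            MetricSurface("SR", ["c1"], {"c2": 1.0})


class TestGeoJSON:
    def test_eea_identifier_parsing(self):
        ring = eea_cell_polygon("10kmE523N201")
        assert ring[0] == [5230.0, 2010.0]
        assert ring[2] == [5240.0, 2020.0]
        assert eea_cell_polygon("freeform-cell") is None

    def test_export_with_partial_geometry(self, tmp_path, caplog):
        import json

        surface = MetricSurface(
            "SR", ["10kmE500N200", "opaque"], {"10kmE500N200": 4.0, "opaque": 2.0}
        )
        geom = eea_grid_geometry(surface.cells)
        path = tmp_path / "sr.csv"
        with caplog.at_level("WARNING", logger="spatdiv"):
            write_surface(surface, path, grid_geometry=geom)
        gj = json.loads(path.with_suffix(".geojson").read_text())
        assert len(gj["features"]) == 1
        assert gj["features"][0]["properties"]["SR"] == 4.0
        assert "opaque" in caplog.text
        # the CSV still carries both cells
        assert len(read_surface(path).values) == 2


def test_occurrence_orderings_deterministic(small_dataset, tmp_path):
    df = small_dataset.occ.to_long_frame().sample(frac=1.0, random_state=0)
    df.to_csv(tmp_path / "occ.csv", index=False)
    a = read_occurrences(tmp_path / "occ.csv")
    b = read_occurrences(tmp_path / "occ.csv")
    assert a.taxa == b.taxa and a.cells == b.cells
    assert np.array_equal(a.presence, b.presence)
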