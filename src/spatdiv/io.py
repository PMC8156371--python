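"""Readers, writers and input alignment.

All tabular formats are plain CSV with headers; trees are Newick.  Surface
CSVs (``cell,metric,value``) encode undefined cells as an *empty* value
field — never 0 — and floats are written with ``repr`` so that
``read(write(x)) == x`` bit-exactly.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path

import dendropy
import pandas as pd

from .datamodel import (
    FLORISTIC_REGIONS,
    MetricSurface,
    OccurrenceMatrix,
    PAMembership,
    Phylogeny,
    RegionMap,
    TraitTable,
)
from .errors import AlignmentError, EmptyInputError, FormatError

log = logging.getLogger("spatdiv")


def _read_csv(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s): {missing}")
    if df.empty:
        raise EmptyInputError(f"{path} has a header but no rows")
    for c in required_cols:
        if (df[c].str.strip() == "").any():
            raise FormatError(f"{path}: empty values in column '{c}'")
    return df


def read_occurrences(path) -> OccurrenceMatrix:
    """Read long-format ``taxon,cell`` occurrence records.

    Duplicate records collapse to one presence (with a warning); taxa and
    cells are ordered lexicographically, so identical input bytes always
    produce identical matrices.
    """
    df = _read_csv(path, ["taxon", "cell"])
    n_dup = len(df) - len(df.drop_duplicates(["taxon", "cell"]))
    if n_dup:
        log.warning("%s: %d duplicate occurrence records collapsed", path, n_dup)
    occ = OccurrenceMatrix.from_records(
        df[["taxon", "cell"]].itertuples(index=False, name=None)
    )
    occ.validate()
    log.info(
        "read %s: %d taxa, %d cells, %d presences",
        path, occ.n_taxa, occ.n_cells, occ.n_presences,
    )
    return occ


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    path = Path(path)
    text = path.read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise FormatError(f"cannot parse Newick in {path}{where}: {exc}")
    phy = Phylogeny(tree)
    log.info(
        "read %s: %d tips, total length %.6g",
        path, phy.n_tips, phy.total_length(),
    )
    return phy


def read_traits(path) -> TraitTable:
    df = _read_csv(path, ["taxon", "trait", "value"])
    return TraitTable(df)


def read_regions(path, vocabulary=FLORISTIC_REGIONS) -> RegionMap:
    df = _read_csv(path, ["cell", "region"])
    return RegionMap(dict(zip(df["cell"], df["region"])), tuple(vocabulary))


def read_pa(path) -> PAMembership:
    df = _read_csv(path, ["cell", "in_pa"])
    bad = sorted(set(df["in_pa"]) - {"0", "1"})
    if bad:
        raise FormatError(f"{path}: in_pa must be 0 or 1, found {bad}")
    return PAMembership({c: v == "1" for c, v in zip(df["cell"], df["in_pa"])})


def align_inputs(occ: OccurrenceMatrix, tree: Phylogeny | None = None,
                 traits: TraitTable | None = None):
    """Reconcile occurrence, tree and trait taxa.

    The tree is pruned to the occurrence taxa (dropped tips are warned
    about, mirroring the subsetting of a national phylogeny to the study
    flora); trait records for unknown taxa are dropped as orphans.  The
    functional stage may legitimately cover only a taxon subset.

    Returns ``(occ, pruned_tree, restricted_traits, report)``.
    """
    occ_taxa = set(occ.taxa)
    report = {"dropped_tips": [], "orphan_trait_taxa": [], "trait_coverage": None}
    out_tree = None
    if tree is not None:
        tips = set(tree.tip_labels())
        if not (tips & occ_taxa):
            raise AlignmentError(
                "tree tips and occurrence taxa are disjoint"
            )
        dropped = sorted(tips - occ_taxa)
        if dropped:
            log.warning("pruning %d tree tips absent from occurrences", len(dropped))
        report["dropped_tips"] = dropped
        out_tree = tree.pruned_to(occ_taxa) if dropped else tree
    out_traits = None
    if traits is not None:
        orphans = sorted(set(traits.taxa) - occ_taxa)
        if orphans:
            log.warning("dropping %d orphan trait taxa", len(orphans))
        report["orphan_trait_taxa"] = orphans
        out_traits = traits.restricted_to(occ_taxa)
        covered = len(set(out_traits.taxa))
        report["trait_coverage"] = (covered, occ.n_taxa)
        log.info("functional stage covers %d of %d taxa", covered, occ.n_taxa)
    return occ, out_tree, out_traits, report


# ---------------------------------------------------------------------------
# metric surfaces

def write_surface(surface: MetricSurface, path, grid_geometry=None,
                  geojson_path=None) -> None:
    """Write a surface as ``cell,metric,value`` CSV (+ optional GeoJSON).

    Undefined cells are written with an empty value field.  When
    ``grid_geometry`` (cell -> polygon ring coordinates) is given, a GeoJSON
    FeatureCollection is also written; cells missing from the geometry go to
    the CSV only, with a warning.
    """
    if not surface.cells:
        raise EmptyInputError("refusing to write an empty surface")
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell", "metric", "value"])
        for cell in surface.cells:
            if cell in surface.values:
                w.writerow([cell, surface.name, repr(surface.values[cell])])
            else:
                w.writerow([cell, surface.name, ""])
    if grid_geometry is not None:
        features = []
        for cell in surface.cells:
            if cell not in grid_geometry:
                log.warning("cell %s missing from grid geometry; CSV only", cell)
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [grid_geometry[cell]],
                    },
                    "properties": {
                        "cell": cell,
                        surface.name: surface.values.get(cell),
                    },
                }
            )
        gj = {"type": "FeatureCollection", "features": features}
        out = Path(geojson_path) if geojson_path else path.with_suffix(".geojson")
        out.write_text(json.dumps(gj))


def read_surface(path) -> MetricSurface:
    """Read a surface CSV written by :func:`write_surface`."""
    path = Path(path)
    cells, values = [], {}
    name = None
    with path.open(newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header != ["cell", "metric", "value"]:
            raise FormatError(
                f"{path}: expected header cell,metric,value, got {header}"
            )
        for row in r:
            if len(row) != 3:
                raise FormatError(f"{path}: malformed row {row}")
            cell, metric, value = row
            if name is None:
                name = metric
            elif metric != name:
                raise FormatError(
                    f"{path}: mixed metrics '{name}' and '{metric}'"
                )
            cells.append(cell)
            if value != "":
                values[cell] = float(value)
    if name is None:
        raise EmptyInputError(f"{path} holds no surface rows")
    return MetricSurface(name, cells, values)


def write_surfaces_long(surfaces, path) -> None:
    """Write several surfaces into one long CSV (cell,metric,value)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell", "metric", "value"])
        for surface in surfaces:
            for cell in surface.cells:
                if cell in surface.values:
                    w.writerow([cell, surface.name, repr(surface.values[cell])])
                else:
                    w.writerow([cell, surface.name, ""])


# ---------------------------------------------------------------------------
# EEA-style cell geometry

_EEA_RE = re.compile(r"^10kmE(\d+)N(\d+)$")


def eea_cell_polygon(cell_id: str, cell_size: float = 10.0):
    """Square polygon ring for an EEA-style id like ``10kmE523N201``.

    Coordinates are in km on the grid's easting/northing axes.  Returns
    ``None`` for identifiers that are not EEA-style.
    """
    m = _EEA_RE.match(cell_id)
    if not m:
        return None
    e, n = int(m.group(1)), int(m.group(2))
    x0, y0 = e * cell_size, n * cell_size
    x1, y1 = x0 + cell_size, y0 + cell_size
    return [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]


def eea_grid_geometry(cells) -> dict:
    """Geometry map for every EEA-style cell id in ``cells``."""
    out = {}
    for c in cells:
        ring = eea_cell_polygon(c)
        if ring is not None:
            out[c] = ring
    return out
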