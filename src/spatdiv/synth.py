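"""Synthetic data emulating a national gridded endemism study.

The generator produces, from one seed, a complete analysis input set:

* an ultrametric dated phylogeny (Yule or birth-death) over ``n_taxa`` tips;
* a taxon-by-cell occurrence matrix on a rectangular grid with EEA-style
  cell identifiers, ranges grown by spreading-dye accretion so that real
  ranges' spatial cohesion is emulated (cohesion 0 degenerates to uniform
  random cell sets — the exchangeable scenario used for null calibration);
* a strongly right-skewed range-size distribution: a narrow-endemic
  fraction with ranges of 1-3 cells plus a log-series tail, mirroring
  floras where roughly half the taxa are narrowly distributed;
* six categorical trait tables with optional multi-valued records and
  partial coverage (emulating trait data available for a taxon subset);
* a 13-region partition of the grid and a protected-area mask;
* optional *planted* endemism centers (narrow endemics concentrated in a
  designated cell block, optionally forming a clade and optionally
  carrying maximal trait diversity) whose ground truth is exported for
  recovery tests.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim
from scipy import stats

from .datamodel import (
    FLORISTIC_REGIONS,
    OccurrenceMatrix,
    PAMembership,
    Phylogeny,
    RegionMap,
    TraitTable,
)
from .errors import ConfigError
from .seeding import derive_seed

import pandas as pd

#: Category vocabulary sizes per trait; the tops align with the
#: "most diverse" bands (e.g. 10 growth forms, 39 petal colors).
DEFAULT_TRAIT_VOCAB = {
    "life_form": 5,
    "longevity": 3,
    "growth_form": 10,
    "dispersal_mode": 7,
    "pollination_type": 4,
    "petal_color": 39,
}


@dataclass
class PlantedCenter:
    """Ground-truth endemism center: narrow endemics packed into a block."""

    block: list            # [(row, col), ...] cells of the center
    n_endemics: int = 20
    range_min: int = 1
    range_max: int = 1
    clade: bool = False           # planted endemics form a clade on the tree
    trait_diversity: bool = False  # planted taxa span full trait vocabularies


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic scenario; the seed is mandatory."""

    seed: int
    n_taxa: int = 931
    grid_rows: int = 46
    grid_cols: int = 45
    endemic_fraction: float = 0.55
    endemic_max_range: int = 3
    logseries_p: float = 0.99
    cohesion: float = 0.8
    tree_model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    trait_vocab: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_VOCAB))
    multi_valued_prob: float = 0.15
    trait_coverage: float = 267 / 931
    planted: PlantedCenter | None = None
    n_regions: int = 13
    pa_rule: str = "random"      # 'random' | 'all' | 'none'
    pa_fraction: float = 0.3
    pa_cover_planted: bool = False
    background_range_min: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("scenario seed is mandatory")
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigError("grid dimensions must be positive")
        if not (0.0 <= self.endemic_fraction <= 1.0):
            raise ConfigError("endemic_fraction must be in [0, 1]")
        if not (0.0 <= self.cohesion <= 1.0):
            raise ConfigError("cohesion must be in [0, 1]")
        if self.tree_model not in ("yule", "birth_death"):
            raise ConfigError(f"unknown tree model '{self.tree_model}'")
        if self.tree_model == "birth_death" and self.death_rate >= self.birth_rate:
            raise ConfigError("birth_death needs death_rate < birth_rate")
        if self.n_regions > len(FLORISTIC_REGIONS):
            raise ConfigError(
                f"at most {len(FLORISTIC_REGIONS)} regions supported"
            )
        if self.planted is not None:
            for r, c in self.planted.block:
                if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                    raise ConfigError(
                        f"planted block cell ({r},{c}) outside the grid"
                    )


@dataclass
class SyntheticDataset:
    occ: OccurrenceMatrix
    tree: Phylogeny
    traits: TraitTable
    regions: RegionMap
    pa: PAMembership
    truth: dict


# ---------------------------------------------------------------------------
# helpers

def cell_id(row: int, col: int) -> str:
    """EEA-style identifier for grid position (row, col)."""
    return f"10kmE{500 + col:03d}N{200 + row:03d}"


_CELL_RE = re.compile(r"^10kmE(\d+)N(\d+)$")


def cell_position(cid: str) -> tuple[int, int]:
    m = _CELL_RE.match(cid)
    e, n = int(m.group(1)), int(m.group(2))
    return n - 200, e - 500


def taxon_names(n: int) -> list[str]:
    return [f"t{i + 1:04d}" for i in range(n)]


def _tree_height(tree: dendropy.Tree) -> float:
    """Root-to-tip height, excluding any root edge above the root."""
    root_edge = tree.seed_node.edge.length or 0.0
    return max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    ) - root_edge


def max_ultrametricity_deviation(phy: Phylogeny) -> float:
    depths = [leaf.distance_from_root() for leaf in phy.tree.leaf_node_iter()]
    return max(depths) - min(depths)


# ---------------------------------------------------------------------------
# tree simulation

def _simulate_raw_tree(n_tips: int, config: ScenarioConfig,
                       rng: random.Random) -> dendropy.Tree:
    death = 0.0 if config.tree_model == "yule" else config.death_rate
    return treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=rng,
    )


def _newick_inner(tree: dendropy.Tree) -> str:
    """Newick string without root-edge length and trailing ';'."""
    s = tree.as_string(
        schema="newick", suppress_rooting=True, suppress_edge_lengths=False,
    ).strip()
    s = s.rstrip(";")
    # strip a root edge length like '(...):0.123'
    i = s.rfind(")")
    return s[: i + 1]


def simulate_tree(config: ScenarioConfig) -> Phylogeny:
    """Ultrametric tree with tips t0001..tNNNN, reproducible from the seed.

    When the scenario plants a clade-restricted endemism center, the
    planted taxa (the last ``n_endemics`` names) form a clade grafted onto
    one background tip, so the clade's MRCA subtends exactly the planted
    endemics.
    """
    rng = random.Random(derive_seed(config.seed, "tree"))
    names = taxon_names(config.n_taxa)
    planted = config.planted
    if planted is None or not planted.clade:
        tree = _simulate_raw_tree(config.n_taxa, config, rng)
        for leaf, name in zip(tree.leaf_node_iter(), names):
            leaf.taxon.label = name
        newick = _newick_inner(tree) + ";"
        return Phylogeny(dendropy.Tree.get(data=newick, schema="newick"))

    k = planted.n_endemics
    if k >= config.n_taxa:
        raise ConfigError("planted endemics must be fewer than n_taxa")
    bg_names, clade_names = names[: config.n_taxa - k], names[config.n_taxa - k:]
    bg = _simulate_raw_tree(len(bg_names) + 1, config, rng)
    leaves = list(bg.leaf_node_iter())
    host = max(leaves, key=lambda l: l.edge.length or 0.0)
    for leaf, name in zip((l for l in leaves if l is not host), bg_names):
        leaf.taxon.label = name
    host.taxon.label = "HOST"
    host_len = host.edge.length
    h = host_len / 2.0

    sub = _simulate_raw_tree(k, config, rng)
    scale = h / _tree_height(sub)
    for e in sub.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    for leaf, name in zip(sub.leaf_node_iter(), clade_names):
        leaf.taxon.label = name

    bg_newick = _newick_inner(bg)
    graft = f"{_newick_inner(sub)}:{host_len - h!r}"
    newick = re.sub(r"HOST:[0-9.eE+-]+", lambda _: graft, bg_newick) + ";"
    return Phylogeny(dendropy.Tree.get(data=newick, schema="newick"))


# ---------------------------------------------------------------------------
# range simulation

def _draw_range_sizes(config: ScenarioConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    n_cells = config.grid_rows * config.grid_cols
    narrow = rng.random(n) < config.endemic_fraction
    sizes = np.empty(n, dtype=int)
    lo = config.background_range_min
    sizes[narrow] = rng.integers(
        max(lo, 1), max(config.endemic_max_range, lo) + 1, size=int(narrow.sum())
    )
    n_wide = int((~narrow).sum())
    if n_wide:
        wide = stats.logser.rvs(
            config.logseries_p, size=n_wide, random_state=rng
        )
        sizes[~narrow] = np.maximum(wide, lo)
    return np.minimum(sizes, n_cells)


def _spreading_dye(size: int, rows: int, cols: int, cohesion: float,
                   rng: np.random.Generator) -> set:
    """Grow a range of ``size`` cells by random adjacent accretion."""
    n_cells = rows * cols
    start = int(rng.integers(n_cells))
    occupied = {start}
    if cohesion <= 0.0:
        extra = rng.choice(
            [c for c in range(n_cells) if c != start],
            size=size - 1, replace=False,
        ) if size > 1 else []
        return occupied | {int(c) for c in extra}

    def neighbors(cell):
        r, c = divmod(cell, cols)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                yield rr * cols + cc

    frontier = set(neighbors(start))
    while len(occupied) < size:
        frontier -= occupied
        if frontier and rng.random() < cohesion:
            new = int(rng.choice(sorted(frontier)))
        else:
            free = [c for c in range(n_cells) if c not in occupied]
            new = int(rng.choice(free))
        occupied.add(new)
        frontier |= set(neighbors(new))
    return occupied


def simulate_ranges(config: ScenarioConfig) -> tuple[OccurrenceMatrix, dict]:
    """Grow every taxon's range; returns the matrix and planted ground truth.

    Drawn range sizes are realized exactly (the accretion loop runs until
    the target size); planted endemics are confined to their block cells.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "ranges"))
    names = taxon_names(config.n_taxa)
    planted = config.planted
    k = planted.n_endemics if planted else 0
    bg_names = names[: config.n_taxa - k]
    planted_names = names[config.n_taxa - k:] if k else []

    rows_idx: dict[str, set] = {}
    sizes = _draw_range_sizes(config, len(bg_names), rng)
    for name, size in zip(bg_names, sizes):
        rows_idx[name] = _spreading_dye(
            int(size), config.grid_rows, config.grid_cols,
            config.cohesion, rng,
        )

    block_cells = []
    if planted:
        block_cells = [r * config.grid_cols + c for r, c in planted.block]
        for name in planted_names:
            r = int(rng.integers(planted.range_min, planted.range_max + 1))
            r = min(r, len(block_cells))
            chosen = rng.choice(block_cells, size=r, replace=False)
            rows_idx[name] = {int(c) for c in chosen}

    all_cells = [
        cell_id(r, c)
        for r in range(config.grid_rows) for c in range(config.grid_cols)
    ]
    records = [
        (name, all_cells[c]) for name, cells in rows_idx.items()
        for c in cells
    ]
    occ = OccurrenceMatrix.from_records(records)
    # re-attach unoccupied grid cells so the full grid is the domain
    missing = sorted(set(all_cells) - set(occ.cells))
    if missing:
        X = np.zeros((len(all_cells), occ.n_taxa), dtype=bool)
        ordered = sorted(all_cells)
        pos = {c: i for i, c in enumerate(ordered)}
        for ci, cell in enumerate(occ.cells):
            X[pos[cell]] = occ.presence[ci]
        occ = OccurrenceMatrix(occ.taxa, ordered, X)
    truth = {
        "planted_taxa": planted_names,
        "planted_cells": sorted(all_cells[c] for c in block_cells),
    }
    return occ, truth


# ---------------------------------------------------------------------------
# traits, regions, protected areas

def simulate_traits(config: ScenarioConfig, taxa=None) -> TraitTable:
    """Categorical trait records with skewed category frequencies.

    Each covered taxon draws one category per trait (two with probability
    ``multi_valued_prob``); coverage emulates trait data existing for only
    a taxon subset.  Planted taxa with ``trait_diversity`` cycle through
    the full vocabulary (two categories each), so a block hosting them
    attains the top trait-richness band for every trait.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "traits"))
    names = taxa if taxa is not None else taxon_names(config.n_taxa)
    planted = config.planted
    planted_set = set()
    if planted and planted.trait_diversity:
        planted_set = set(names[len(names) - planted.n_endemics:])
    n_cover = int(round(config.trait_coverage * len(names)))
    covered = set(
        rng.choice(names, size=min(n_cover, len(names)), replace=False)
    ) | planted_set

    records = []
    for trait, vocab in config.trait_vocab.items():
        cats = [f"{trait}_{i + 1:02d}" for i in range(vocab)]
        weights = 0.7 ** np.arange(vocab)
        weights /= weights.sum()
        slot = 0
        for name in names:
            if name not in covered:
                continue
            if name in planted_set:
                records.append((name, trait, cats[slot % vocab]))
                records.append((name, trait, cats[(slot + 1) % vocab]))
                slot += 2
            else:
                n_vals = 2 if rng.random() < config.multi_valued_prob else 1
                n_vals = min(n_vals, vocab)
                for c in rng.choice(vocab, size=n_vals, replace=False,
                                    p=weights):
                    records.append((name, trait, cats[int(c)]))
    return TraitTable(
        pd.DataFrame(records, columns=["taxon", "trait", "value"])
    )


def simulate_regions(config: ScenarioConfig) -> RegionMap:
    """Voronoi partition of the grid into contiguous region blocks."""
    rng = np.random.default_rng(derive_seed(config.seed, "regions"))
    n = config.n_regions
    seeds = rng.choice(
        config.grid_rows * config.grid_cols, size=n, replace=False
    )
    seed_pos = [divmod(int(s), config.grid_cols) for s in seeds]
    mapping = {}
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            dists = [abs(r - sr) + abs(c - sc) for sr, sc in seed_pos]
            mapping[cell_id(r, c)] = FLORISTIC_REGIONS[int(np.argmin(dists))]
    return RegionMap(mapping, FLORISTIC_REGIONS[:n] if n < 13 else FLORISTIC_REGIONS)


def simulate_pa(config: ScenarioConfig, cells, truth=None) -> PAMembership:
    rng = np.random.default_rng(derive_seed(config.seed, "pa"))
    if config.pa_rule == "all":
        mapping = {c: True for c in cells}
    elif config.pa_rule == "none":
        mapping = {c: False for c in cells}
    elif config.pa_rule == "random":
        draws = rng.random(len(cells)) < config.pa_fraction
        mapping = {c: bool(d) for c, d in zip(cells, draws)}
    else:
        raise ConfigError(f"unknown pa_rule '{config.pa_rule}'")
    if config.pa_cover_planted and truth:
        for c in truth.get("planted_cells", []):
            mapping[c] = True
    return PAMembership(mapping)


# ---------------------------------------------------------------------------
# whole datasets

def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    occ, truth = simulate_ranges(config)
    tree = simulate_tree(config)
    traits = simulate_traits(config)
    regions = simulate_regions(config)
    pa = simulate_pa(config, occ.cells, truth)
    truth["seed"] = config.seed
    return SyntheticDataset(occ, tree, traits, regions, pa, truth)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write occ.csv, tree.nwk, traits.csv, regions.csv, pa.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    occ_path = outdir / "occ.csv"
    ds.occ.to_long_frame().to_csv(occ_path, index=False)
    paths["occ"] = occ_path
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(ds.tree.as_newick())
    paths["tree"] = tree_path
    traits_path = outdir / "traits.csv"
    ds.traits.frame.to_csv(traits_path, index=False)
    paths["traits"] = traits_path
    regions_path = outdir / "regions.csv"
    pd.DataFrame(
        sorted(ds.regions.mapping.items()), columns=["cell", "region"]
    ).to_csv(regions_path, index=False)
    paths["regions"] = regions_path
    pa_path = outdir / "pa.csv"
    pd.DataFrame(
        [(c, int(v)) for c, v in sorted(ds.pa.mapping.items())],
        columns=["cell", "in_pa"],
    ).to_csv(pa_path, index=False)
    paths["pa"] = pa_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(ds.truth, indent=2))
    paths["truth"] = truth_path
    return paths
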