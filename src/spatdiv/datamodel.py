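"""Core in-memory containers for the gridded diversity analysis.

The substrate of every metric is a taxon-by-cell presence/absence matrix
(:class:`OccurrenceMatrix`).  Phylogenetic metrics additionally need a rooted
tree with branch lengths (:class:`Phylogeny`, a thin wrapper over a dendropy
tree), and the functional stage a long-format categorical trait table
(:class:`TraitTable`).  Per-cell scalar results travel as
:class:`MetricSurface`, which distinguishes *undefined* cells (e.g. corrected
weighted endemism where richness is zero) from cells whose value is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

log = logging.getLogger("spatdiv")

#: The 13 floristic regions of Greece used for regional summaries.
FLORISTIC_REGIONS = (
    "NE", "NC", "EC", "NPi", "SPi", "StE", "Pe",
    "IoI", "NAe", "WAe", "EAe", "Kik", "KK",
)

#: Closed vocabulary of categorical traits.
TRAIT_NAMES = (
    "life_form", "longevity", "growth_form",
    "dispersal_mode", "pollination_type", "petal_color",
)


class OccurrenceMatrix:
    """Taxon x grid-cell presence/absence incidence.

    Parameters
    ----------
    taxa, cells
        Unique identifier lists.  Orderings are preserved as given;
        constructors that read data sort them lexicographically so that
        identical input bytes yield identical orderings.
    presence
        Boolean array of shape ``(n_cells, n_taxa)``.
    """

    def __init__(self, taxa, cells, presence):
        self.taxa = list(taxa)
        self.cells = list(cells)
        self.presence = np.asarray(presence, dtype=bool)
        if self.presence.shape != (len(self.cells), len(self.taxa)):
            raise ValidationError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.cells)} cells x {len(self.taxa)} taxa"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("taxon identifiers are not unique")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("cell identifiers are not unique")
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "OccurrenceMatrix":
        """Build from an iterable of ``(taxon, cell)`` pairs.

        Duplicates collapse to a single presence; taxa and cells are sorted
        lexicographically.
        """
        pairs = set()
        taxa, cells = set(), set()
        for taxon, cell in records:
            taxa.add(taxon)
            cells.add(cell)
            pairs.add((taxon, cell))
        taxa = sorted(taxa)
        cells = sorted(cells)
        ti = {t: i for i, t in enumerate(taxa)}
        ci = {c: i for i, c in enumerate(cells)}
        X = np.zeros((len(cells), len(taxa)), dtype=bool)
        for taxon, cell in pairs:
            X[ci[cell], ti[taxon]] = True
        return cls(taxa, cells, X)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_presences(self) -> int:
        return int(self.presence.sum())

    def range_sizes(self) -> np.ndarray:
        """Per-taxon range size r_s: the number of occupied cells."""
        return self.presence.sum(axis=0)

    def cell_richness(self) -> np.ndarray:
        """Per-cell taxon count."""
        return self.presence.sum(axis=1)

    def taxa_of_cell(self, cell: str) -> list[str]:
        row = self.presence[self._cell_index[cell]]
        return [self.taxa[i] for i in np.flatnonzero(row)]

    def cells_of_taxon(self, taxon: str) -> list[str]:
        col = self.presence[:, self._taxon_index[taxon]]
        return [self.cells[i] for i in np.flatnonzero(col)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (taxon, cell) presence records, row-sorted."""
        cell_idx, taxon_idx = np.nonzero(self.presence)
        df = pd.DataFrame(
            {
                "taxon": [self.taxa[i] for i in taxon_idx],
                "cell": [self.cells[i] for i in cell_idx],
            }
        )
        return df.sort_values(["taxon", "cell"], ignore_index=True)

    def subset_taxa(self, keep) -> "OccurrenceMatrix":
        keep = [t for t in self.taxa if t in set(keep)]
        cols = [self._taxon_index[t] for t in keep]
        return OccurrenceMatrix(keep, self.cells, self.presence[:, cols])

    def validate(self) -> None:
        """Raise if any taxon occupies no cell; warn about empty cells."""
        ranges = self.range_sizes()
        if (ranges < 1).any():
            bad = [self.taxa[i] for i in np.flatnonzero(ranges < 1)]
            raise ValidationError(f"taxa with empty ranges: {bad[:10]}")
        empty = int((self.cell_richness() == 0).sum())
        if empty:
            log.warning("%d cells host no taxa", empty)

    def __repr__(self):
        return (
            f"OccurrenceMatrix({self.n_taxa} taxa x {self.n_cells} cells, "
            f"{self.n_presences} presences)"
        )


class Phylogeny:
    """A rooted tree with branch lengths whose tips name analysis taxa."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True    # rooted by contract
        self._validate()

    def _validate(self) -> None:
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels in tree")
        missing = [
            e for e in self.tree.preorder_edge_iter()
            if e.head_node.parent_node is not None and e.length is None
        ]
        if missing:
            raise ValidationError(
                "tree has branches without lengths; branch lengths are "
                "required for PD/PE"
            )
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValidationError(f"negative branch length {e.length}")
        if self.total_length() <= 0:
            raise ValidationError("total tree length must be > 0")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def total_length(self) -> float:
        """Sum of all branch lengths (root edge included when present)."""
        return float(
            sum(e.length for e in self.tree.preorder_edge_iter()
                if e.length is not None)
        )

    def pruned_to(self, taxa) -> "Phylogeny":
        """Return a copy retaining only tips named in ``taxa``."""
        keep = set(taxa)
        present = [l for l in self.tip_labels() if l in keep]
        if not present:
            raise AlignmentError("no tree tips overlap the requested taxa")
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(present)
        return Phylogeny(clone)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    def __repr__(self):
        return f"Phylogeny({self.n_tips} tips, length {self.total_length():.4g})"


class TraitTable:
    """Long-format categorical trait records with union semantics.

    A taxon may carry several categories of the same trait (e.g. two petal
    colors); each (taxon, trait, value) triple is kept once.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"taxon", "trait", "value"}
        if not required.issubset(frame.columns):
            raise ValidationError(
                f"trait table needs columns {sorted(required)}"
            )
        df = frame[["taxon", "trait", "value"]].copy()
        df["value"] = df["value"].astype(str).str.strip().str.lower()
        df = df.drop_duplicates(ignore_index=True)
        self.frame = df.sort_values(
            ["taxon", "trait", "value"], ignore_index=True
        )

    @property
    def taxa(self) -> list[str]:
        return sorted(self.frame["taxon"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    def categories(self, trait: str) -> list[str]:
        return sorted(
            self.frame.loc[self.frame["trait"] == trait, "value"].unique()
        )

    def taxon_categories(self, trait: str) -> dict[str, set]:
        """Map taxon -> set of categories it carries for ``trait``."""
        sub = self.frame[self.frame["trait"] == trait]
        return {t: set(g["value"]) for t, g in sub.groupby("taxon")}

    def restricted_to(self, taxa) -> "TraitTable":
        keep = set(taxa)
        return TraitTable(self.frame[self.frame["taxon"].isin(keep)])

    def __len__(self):
        return len(self.frame)


@dataclass
class MetricSurface:
    """One scalar per grid cell for a named metric.

    ``values`` holds *defined* cells only; any cell of the domain absent from
    ``values`` is undefined (CWE at richness 0, PD of an empty cell, SES
    where the null does not vary).  Undefined is never encoded as 0.
    """

    name: str
    cells: list[str]
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        extra = set(self.values) - set(self.cells)
        if extra:
            raise ValidationError(
                f"surface '{self.name}' holds values for cells outside its "
                f"domain: {sorted(extra)[:5]}"
            )

    def defined_cells(self) -> list[str]:
        return [c for c in self.cells if c in self.values]

    def undefined_cells(self) -> list[str]:
        return [c for c in self.cells if c not in self.values]

    def defined_values(self) -> np.ndarray:
        return np.array([self.values[c] for c in self.defined_cells()])

    def as_series(self) -> pd.Series:
        """Full-domain series with NaN at undefined cells."""
        return pd.Series(
            [self.values.get(c, np.nan) for c in self.cells],
            index=self.cells, name=self.name, dtype=float,
        )

    def __getitem__(self, cell: str) -> float:
        return self.values[cell]

    def __contains__(self, cell: str) -> bool:
        return cell in self.values


@dataclass
class RegionMap:
    """Cell -> floristic-region label with a closed vocabulary."""

    mapping: dict[str, str]
    vocabulary: tuple = FLORISTIC_REGIONS

    def __post_init__(self):
        vocab = set(self.vocabulary)
        bad = sorted({r for r in self.mapping.values() if r not in vocab})
        if bad:
            raise ValidationError(f"unknown region labels: {bad}")

    def region_of(self, cell: str) -> str:
        return self.mapping[cell]

    def __contains__(self, cell):
        return cell in self.mapping


@dataclass
class PAMembership:
    """Cell -> boolean protected-area (Natura 2000) membership flag."""

    mapping: dict[str, bool]

    def inside(self, cell: str) -> bool:
        return bool(self.mapping[cell])

    def __contains__(self, cell):
        return cell in self.mapping


@dataclass
class NullEnsemble:
    """Per-cell summary of a permutation/randomization null for one metric.

    p-values use the +1 permutation convention: with ``n_perm`` replicates
    the one-tailed floor is ``1/(n_perm+1)``; the two-tailed p doubles the
    smaller tail and is capped at 1.  Ties between observed and null count
    toward both tails (conservative).
    """

    metric: str
    cells: list[str]
    observed: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    rank: dict[str, int]          # number of null values strictly below obs
    p_value: dict[str, float]     # two-tailed
    n_permutations: int
    algorithm: str
    seed: int
    ses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        floor = 1.0 / (self.n_permutations + 1)
        for c, p in self.p_value.items():
            if not (floor - 1e-12 <= p <= 1 + 1e-12):
                raise ValidationError(
                    f"p-value {p} for cell {c} outside "
                    f"[{floor}, 1]"
                )
            r = self.rank[c]
            if not (0 <= r <= self.n_permutations):
                raise ValidationError(f"rank {r} for cell {c} out of range")

    def significance(self, alpha: float = 0.05) -> dict[str, str]:
        """Classify each cell: 'high', 'low', 'ns' or 'undefined'."""
        out = {}
        for c in self.cells:
            if c not in self.p_value:
                out[c] = "undefined"
            elif self.p_value[c] <= alpha:
                out[c] = (
                    "high" if self.observed[c] > self.null_mean[c] else "low"
                )
            else:
                out[c] = "ns"
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        sig = self.significance()
        for c in self.cells:
            rows.append(
                {
                    "cell": c,
                    "observed": self.observed.get(c, np.nan),
                    "null_mean": self.null_mean.get(c, np.nan),
                    "null_sd": self.null_sd.get(c, np.nan),
                    "rank": self.rank.get(c, np.nan),
                    "p_value": self.p_value.get(c, np.nan),
                    "ses": self.ses.get(c, np.nan),
                    "class": sig[c],
                }
            )
        df = pd.DataFrame(rows)
        df.insert(0, "metric", self.metric)
        return df
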