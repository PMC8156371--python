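"""Per-cell categorical trait richness and "most diverse" cell flags.

For each of six traits (life form, longevity, growth form, dispersal mode,
pollination type, petal color) the trait richness of a cell is the number of
*distinct* categories carried by the taxa present there, with union
semantics for multi-valued taxa.  Cells whose count falls inside a
trait-specific band are flagged "most diverse"; the per-region breakdown of
flagged cells mirrors the study's regional summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import OccurrenceMatrix, RegionMap, TraitTable, TRAIT_NAMES
from .errors import ConfigError, EmptyInputError, ValidationError

log = logging.getLogger("spatdiv")

#: Default "most diverse" bands (inclusive count intervals) per trait,
#: matching the bands reported for the study flora.
DEFAULT_BANDS = {
    "life_form": (5, 5),
    "growth_form": (8, 10),
    "longevity": (3, 3),
    "dispersal_mode": (6, 7),
    "pollination_type": (3, 4),
    "petal_color": (26, 39),
}


@dataclass
class TraitRichnessSurface:
    """Per-cell distinct-category counts for one trait.

    ``counts`` covers every cell of the occurrence domain; ``covered_cells``
    are those hosting at least one taxon with a record for this trait —
    the default denominator for "proportion of cells" summaries.
    """

    trait: str
    cells: list[str]
    counts: dict[str, int]
    covered_cells: set = field(default_factory=set)

    def __getitem__(self, cell):
        return self.counts[cell]


@dataclass
class FlaggedSurface:
    trait: str
    band: tuple
    flagged: set
    proportion: float
    denominator: int


def trait_richness(occ: OccurrenceMatrix, traits: TraitTable,
                   trait: str) -> TraitRichnessSurface:
    """Distinct-category count per cell for one trait (union semantics)."""
    if trait not in TRAIT_NAMES:
        raise ConfigError(
            f"unknown trait '{trait}'; expected one of {list(TRAIT_NAMES)}"
        )
    taxon_cats = traits.taxon_categories(trait)
    taxon_cats = {t: c for t, c in taxon_cats.items() if t in set(occ.taxa)}
    if not taxon_cats:
        raise EmptyInputError(f"no taxa carry records for trait '{trait}'")
    uncovered = occ.n_taxa - len(taxon_cats)
    if uncovered:
        log.info(
            "trait '%s': %d of %d taxa lack records and are ignored",
            trait, uncovered, occ.n_taxa,
        )
    counts, covered = {}, set()
    for ci, cell in enumerate(occ.cells):
        cats = set()
        any_covered = False
        row = occ.presence[ci]
        for ti, taxon in enumerate(occ.taxa):
            if row[ti] and taxon in taxon_cats:
                cats |= taxon_cats[taxon]
                any_covered = True
        counts[cell] = len(cats)
        if any_covered:
            covered.add(cell)
    return TraitRichnessSurface(trait, list(occ.cells), counts, covered)


def flag_most_diverse(surface: TraitRichnessSurface,
                      band: tuple | None = None,
                      denominator: str = "covered") -> FlaggedSurface:
    """Flag cells whose count falls in the (inclusive) band.

    ``denominator`` chooses the basis of the reported proportion:
    ``covered`` (cells with at least one trait-covered taxon, default) or
    ``all`` (every cell of the domain).
    """
    if band is None:
        band = DEFAULT_BANDS[surface.trait]
    lo, hi = band
    if lo > hi:
        raise ConfigError(f"empty band {band}")
    if denominator not in ("covered", "all"):
        raise ConfigError("denominator must be 'covered' or 'all'")
    basis = (
        sorted(surface.covered_cells) if denominator == "covered"
        else list(surface.cells)
    )
    if not basis:
        raise EmptyInputError("no cells to evaluate")
    flagged = {c for c in basis if lo <= surface.counts[c] <= hi}
    observed_max = max(surface.counts[c] for c in basis)
    if not flagged and lo > observed_max:
        log.warning(
            "band %s lies above the observed maximum %d for trait '%s'",
            band, observed_max, surface.trait,
        )
    return FlaggedSurface(
        trait=surface.trait, band=(lo, hi), flagged=flagged,
        proportion=len(flagged) / len(basis), denominator=len(basis),
    )


def regional_share(flagged, regions: RegionMap) -> pd.Series:
    """Share of flagged cells per region, sorted descending; sums to 1."""
    cells = sorted(flagged.flagged if isinstance(flagged, FlaggedSurface)
                   else flagged)
    if not cells:
        raise EmptyInputError("no flagged cells to summarize")
    unmapped = [c for c in cells if c not in regions]
    if unmapped:
        raise ValidationError(
            f"flagged cells without a region: {unmapped[:10]}"
        )
    counts = pd.Series([regions.region_of(c) for c in cells]).value_counts()
    share = (counts / len(cells)).sort_values(ascending=False)
    share.index.name = "region"
    share.name = "share"
    return share
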