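"""Diversity-facet to CICES ecosystem-service crosswalk.

Eight indicator letters stand for the mapped diversity facets — T taxonomic
diversity, P phylogenetic diversity, and six trait facets (G growth form,
L life form, LV longevity, D dispersal mode, PL pollination type, C petal
color).  Each CICES class (dotted code, e.g. 2.2.2.1 pollination) lists the
letters for which it is a relevant service; a class is relevant in a cell
as soon as one of its letters is flagged there (OR semantics).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError

INDICATOR_LETTERS = ("T", "P", "G", "L", "LV", "D", "PL", "C")

SECTIONS = (
    "provisioning_biotic",
    "regulating_maintenance_biotic",
    "cultural_biotic",
)

#: Trait name -> indicator letter.
TRAIT_LETTER = {
    "life_form": "L",
    "growth_form": "G",
    "longevity": "LV",
    "dispersal_mode": "D",
    "pollination_type": "PL",
    "petal_color": "C",
}


@dataclass(frozen=True)
class CrosswalkRow:
    section: str
    description: str
    code: str
    indicators: frozenset


@dataclass
class CICESCrosswalk:
    rows: list

    def __post_init__(self):
        codes = [r.code for r in self.rows]
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate CICES codes in crosswalk")
        for r in self.rows:
            if r.section not in SECTIONS:
                raise ValidationError(f"unknown section '{r.section}'")
            if not r.indicators:
                raise ValidationError(f"row {r.code} has no indicators")
            bad = set(r.indicators) - set(INDICATOR_LETTERS)
            if bad:
                raise ValidationError(
                    f"row {r.code} has unknown indicator letters {sorted(bad)}"
                )

    def codes(self) -> list[str]:
        return sorted(r.code for r in self.rows)

    def row(self, code: str) -> CrosswalkRow:
        for r in self.rows:
            if r.code == code:
                return r
        raise KeyError(code)

    def section_counts(self) -> dict[str, int]:
        out = {s: 0 for s in SECTIONS}
        for r in self.rows:
            out[r.section] += 1
        return out

    def to_csv(self, path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["section", "description", "code", "indicators"])
            for r in self.rows:
                letters = sorted(r.indicators,
                                 key=INDICATOR_LETTERS.index)
                w.writerow([r.section, r.description, r.code, "|".join(letters)])

    @classmethod
    def from_csv(cls, path) -> "CICESCrosswalk":
        rows = []
        with Path(path).open(newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    CrosswalkRow(
                        section=rec["section"],
                        description=rec["description"],
                        code=rec["code"],
                        indicators=frozenset(rec["indicators"].split("|")),
                    )
                )
        return cls(rows)


_BUILTIN = [
    ("provisioning_biotic",
     "Fibers and other materials from wild plants for direct use or "
     "processing (excluding genetic materials)",
     "1.1.5.2", "G L"),
    ("provisioning_biotic",
     "Seeds, spores and other plant materials collected for maintaining or "
     "establishing a population",
     "1.2.1.1", "G L"),
    ("provisioning_biotic",
     "Higher and lower plants (whole organisms) used to breed new strains "
     "or varieties",
     "1.2.1.2", "T P"),
    ("provisioning_biotic",
     "Individual genes extracted from higher and lower plants for the "
     "design and construction of new biological entities",
     "1.2.1.3", "T P"),
    ("regulating_maintenance_biotic",
     "Pollination (or 'gamete' dispersal in a marine context)",
     "2.2.2.1", "D C PL"),
    ("regulating_maintenance_biotic",
     "Maintaining nursery populations and habitats (including gene pool "
     "protection)",
     "2.2.2.3", "T P G D"),
    ("regulating_maintenance_biotic",
     "Control of erosion rates",
     "2.2.1.1", "G L LV"),
    ("cultural_biotic",
     "Characteristics of living systems that enable activities promoting "
     "health, recuperation, or enjoyment through passive or observational "
     "interactions",
     "3.1.1.2", "T P G L C PL"),
    ("cultural_biotic",
     "Characteristics of living systems that enable scientific "
     "investigation or the creation of traditional ecological knowledge",
     "3.1.2.1", "T P PL"),
    ("cultural_biotic",
     "Characteristics of living systems that enable education and training",
     "3.1.2.2", "T P G L D C"),
    ("cultural_biotic",
     "Characteristics of living systems that enable aesthetic experiences",
     "3.1.2.4", "G L D C"),
]


def builtin_crosswalk() -> CICESCrosswalk:
    """The built-in 11-class crosswalk for cliff-and-scree plant diversity."""
    return CICESCrosswalk(
        [CrosswalkRow(s, d, c, frozenset(ind.split()))
         for s, d, c, ind in _BUILTIN]
    )


def relevant_es(cell_flags: dict, crosswalk: CICESCrosswalk | None = None) -> list[str]:
    """CICES codes relevant to a cell given its facet flags.

    ``cell_flags`` maps indicator letters to booleans; missing letters are
    treated as False, unknown letters are an error.  A class is relevant
    iff at least one of its indicator letters is flagged.
    """
    bad = sorted(set(cell_flags) - set(INDICATOR_LETTERS))
    if bad:
        raise ValidationError(f"unknown indicator letters: {bad}")
    if crosswalk is None:
        crosswalk = builtin_crosswalk()
    active = {l for l, v in cell_flags.items() if v}
    return sorted(r.code for r in crosswalk.rows if r.indicators & active)


def facet_flags(cell, hotspots=None, diverse_flags=None) -> dict:
    """Default per-cell facet flags from analysis outputs.

    T is flagged when the cell sits in an SR or CWE L1 hotspot, P for PD or
    PE; each trait letter when the cell carries that trait's most-diverse
    flag.  ``hotspots`` maps metric name -> HotspotSet (or cell set),
    ``diverse_flags`` maps trait name -> flagged cell set.
    """
    hotspots = hotspots or {}
    diverse_flags = diverse_flags or {}
    flags = {l: False for l in INDICATOR_LETTERS}
    for metric, hs in hotspots.items():
        members = getattr(hs, "members", hs)
        if cell in members:
            if metric in ("SR", "CWE"):
                flags["T"] = True
            elif metric in ("PD", "PE"):
                flags["P"] = True
    for trait, cells in diverse_flags.items():
        members = getattr(cells, "flagged", cells)
        if cell in members:
            flags[TRAIT_LETTER[trait]] = True
    return flags
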