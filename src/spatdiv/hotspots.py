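"""Hotspot delineation, class binning and protected-area overlap.

A metric's L1 hotspots are the cells in its highest 1% of values (empirical
quantile threshold, ties included).  Map-style 5-class bins and cell-level
protected-area accounting reproduce the overlap reporting of the study
("are all medium-or-better cells inside the Natura 2000 network?").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MetricSurface, PAMembership
from .errors import ConfigError, EmptyInputError, ValidationError

log = logging.getLogger("spatdiv")

CLASS_LABELS = ("very_low", "low", "medium", "high", "very_high")


@dataclass
class HotspotSet:
    metric: str
    level: float
    threshold: float
    members: set

    def __contains__(self, cell):
        return cell in self.members

    def __len__(self):
        return len(self.members)


def hotspot_l1(surface: MetricSurface, level: float = 0.99) -> HotspotSet:
    """Cells at or above the empirical ``level``-quantile of the surface.

    The threshold is the linear-interpolation quantile over defined cells;
    every cell with value >= threshold is a member, so ties at the
    threshold can push the set beyond the nominal 1%.
    """
    defined = surface.defined_cells()
    if not defined:
        raise EmptyInputError(
            f"surface '{surface.name}' has no defined cells"
        )
    if not (0.0 <= level <= 1.0):
        raise ConfigError("level must be in [0, 1]")
    values = surface.defined_values()
    threshold = float(np.quantile(values, level))
    members = {c for c in defined if surface.values[c] >= threshold}
    log.info(
        "%s hotspots at level %.3g: threshold %.6g, %d cells",
        surface.name, level, threshold, len(members),
    )
    return HotspotSet(surface.name, level, threshold, members)


def bin_classes(surface: MetricSurface, scheme: str = "quantile_5",
                breaks=None) -> dict[str, str]:
    """Bin defined cells into five classes (very_low .. very_high).

    ``quantile_5`` uses the 20/40/60/80% quantiles, ``equal_interval_5``
    equal-width intervals, ``custom`` the four ascending interior
    ``breaks``.  The break values are logged; a constant surface collapses
    into a single class with a warning.
    """
    defined = surface.defined_cells()
    if len(defined) < len(CLASS_LABELS):
        raise EmptyInputError(
            "need at least as many defined cells as classes"
        )
    values = surface.defined_values()
    if scheme == "quantile_5":
        cuts = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    elif scheme == "equal_interval_5":
        lo, hi = values.min(), values.max()
        cuts = lo + (hi - lo) * np.array([0.2, 0.4, 0.6, 0.8])
    elif scheme == "custom":
        if breaks is None or len(breaks) != 4:
            raise ConfigError("custom scheme needs exactly 4 interior breaks")
        cuts = np.asarray(breaks, dtype=float)
        if not np.all(np.diff(cuts) > 0):
            raise ConfigError(f"breaks must be strictly increasing: {breaks}")
    else:
        raise ConfigError(f"unknown binning scheme '{scheme}'")
    if values.min() == values.max():
        log.warning(
            "surface '%s' is constant; all cells fall in one class",
            surface.name,
        )
    log.info("class breaks for %s (%s): %s", surface.name, scheme, list(cuts))
    idx = np.searchsorted(cuts, values, side="right")
    return {c: CLASS_LABELS[i] for c, i in zip(defined, idx)}


def pa_overlap(classed, pa: PAMembership) -> pd.DataFrame:
    """Protected-area overlap accounting for classed cells or a hotspot set.

    Returns one row per class with inside/outside counts and the outside
    cell identities.  For a :class:`HotspotSet` the single class is
    ``hotspot``.
    """
    if isinstance(classed, HotspotSet):
        classed = {c: "hotspot" for c in sorted(classed.members)}
    if not classed:
        raise EmptyInputError("nothing to overlap")
    unmapped = sorted(c for c in classed if c not in pa)
    if unmapped:
        raise ValidationError(
            f"cells without protected-area membership: {unmapped[:10]}"
        )
    order = {label: i for i, label in enumerate(CLASS_LABELS + ("hotspot",))}
    rows = []
    for cls in sorted(set(classed.values()), key=lambda x: order.get(x, 99)):
        cells = sorted(c for c, v in classed.items() if v == cls)
        inside = [c for c in cells if pa.inside(c)]
        outside = [c for c in cells if not pa.inside(c)]
        rows.append(
            {
                "class": cls,
                "n_cells": len(cells),
                "n_inside": len(inside),
                "n_outside": len(outside),
                "outside_cells": ";".join(outside),
            }
        )
    return pd.DataFrame(rows)


def all_inside(overlap: pd.DataFrame, classes=("medium", "high", "very_high")) -> bool:
    """Headline check: are all cells of the given classes inside the PA network?"""
    sub = overlap[overlap["class"].isin(classes)]
    return bool((sub["n_outside"] == 0).all())
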