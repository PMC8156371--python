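"""Map the diversity facets to CICES ecosystem-service classes per cell.

Flags each cell's elevated facets (taxonomic / phylogenetic hotspot
membership, most-diverse trait bands), applies the built-in 11-class
crosswalk, and writes the per-cell ES relevance table.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import RESULTS
from spatdiv.crosswalk import builtin_crosswalk, facet_flags, relevant_es


def main():
    xwalk = builtin_crosswalk()
    counts = xwalk.section_counts()
    print(f"crosswalk: {len(xwalk.codes())} CICES classes "
          f"({counts['provisioning_biotic']} provisioning, "
          f"{counts['regulating_maintenance_biotic']} regulating/maintenance, "
          f"{counts['cultural_biotic']} cultural)")
    xwalk.to_csv(RESULTS / "cices_crosswalk.csv")

    hotspots_frame = pd.read_csv(RESULTS / "hotspots.csv")
    hotspots = {
        metric: set(group["cell"])
        for metric, group in hotspots_frame.groupby("metric")
    }
    traits_frame = pd.read_csv(RESULTS / "trait_richness.csv")
    diverse = {
        trait: set(group.loc[group["most_diverse"], "cell"])
        for trait, group in traits_frame.groupby("trait")
    }
    cells = sorted(set(traits_frame["cell"]))

    rows = []
    class_hits = Counter()
    for cell in cells:
        flags = facet_flags(cell, hotspots=hotspots, diverse_flags=diverse)
        codes = relevant_es(flags, xwalk)
        class_hits.update(codes)
        rows.append({
            "cell": cell,
            "flags": "|".join(l for l, v in flags.items() if v),
            "relevant_codes": "|".join(codes),
            "n_relevant": len(codes),
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "es_relevance.csv", index=False)
    n_any = int((frame["n_relevant"] > 0).sum())
    print(f"{n_any} of {len(cells)} cells have at least one relevant ES class")
    for code, n in class_hits.most_common(3):
        print(f"  most frequent: {code} "
              f"({xwalk.row(code).description[:50]}...) in {n} cells")
    print(f"wrote cices_crosswalk.csv and es_relevance.csv "
          f"under {RESULTS.name}/")


if __name__ == "__main__":
    main()
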