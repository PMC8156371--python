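"""L1 hotspots, 5-class endemism maps and protected-area overlap.

Delineates the top-1% hotspot cells for SR, CWE, PD and PE, bins the CWE
and PE surfaces into five quantile classes, and reports how much of each
falls inside the protected-area network — including the headline check
whether every medium-or-better endemism cell is protected.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import DATA, RESULTS
from spatdiv.hotspots import all_inside, bin_classes, hotspot_l1, pa_overlap
from spatdiv.io import read_pa, read_surface


def main():
    pa = read_pa(DATA / "pa.csv")
    hotspot_rows, overlap_frames = [], []
    for metric in ("sr", "cwe", "pd", "pe"):
        surface = read_surface(RESULTS / f"surface_{metric}.csv")
        hs = hotspot_l1(surface, level=0.99)
        inside = sum(1 for c in hs.members if pa.inside(c))
        print(f"{surface.name}: threshold {hs.threshold:.4g}, "
              f"{len(hs.members)} hotspot cells, {inside} inside PAs")
        hotspot_rows += [
            {"metric": surface.name, "threshold": hs.threshold, "cell": c,
             "in_pa": pa.inside(c)}
            for c in sorted(hs.members)
        ]
        rep = pa_overlap(hs, pa)
        rep.insert(0, "metric", f"{surface.name}_L1")
        overlap_frames.append(rep)

    for metric in ("cwe", "pe"):
        surface = read_surface(RESULTS / f"surface_{metric}.csv")
        classed = bin_classes(surface, scheme="quantile_5")
        rep = pa_overlap(classed, pa)
        rep.insert(0, "metric", surface.name)
        overlap_frames.append(rep)
        verdict = "all" if all_inside(rep) else "not all"
        print(f"{surface.name} 5-class map: {verdict} medium/high/very_high "
              f"cells inside the protected-area network")

    pd.DataFrame(hotspot_rows).to_csv(RESULTS / "hotspots.csv", index=False)
    pd.concat(overlap_frames, ignore_index=True).to_csv(
        RESULTS / "pa_overlap.csv", index=False
    )
    print(f"wrote hotspots.csv and pa_overlap.csv under {RESULTS.name}/")


if __name__ == "__main__":
    main()
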