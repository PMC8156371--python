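# spatdiv

Grid-based spatial analysis of taxonomic, phylogenetic and functional plant
diversity, written for conservation studies of highly endemic floras — the
motivating system is the chasmophyte (cliff-and-scree) flora of Greece,
mapped on the 10 km × 10 km EEA reference grid, but every stage runs on any
taxon-by-cell occurrence table, dated phylogeny and categorical trait table.

The package computes, per grid cell *c* holding taxa *s* with range sizes
*r_s* (occupied-cell counts):

- **SR** — species richness, the number of taxa present;
- **WE** — weighted endemism, Σ_s 1/r_s (range-size rarity);
- **CWE** — corrected weighted endemism, WE/SR: the mean inverse range
  size, isolating endemism from richness (undefined where SR = 0);
- **PD** — Faith's phylogenetic diversity, Σ_b L_b over all branches *b*
  with a descendant tip in the cell (root-inclusive);
- **PE** — phylogenetic endemism, Σ_b L_b / R_b, where R_b is the number of
  cells holding a descendant tip of *b* — the phylogenetic analogue of WE;
- **PD_SES** — the standardized effect size (PD − mean PD_null)/sd PD_null
  under a fixed-richness null; |SES| ≥ 1.96 marks significant phylogenetic
  overdispersion (+) or clustering (−);
- per-trait **categorical richness** for six functional traits (life form,
  longevity, growth form, dispersal mode, pollination type, petal color),
  with "most diverse" band flags and per-region breakdowns.

Around these sit a permutation-null significance test for CWE (curveball
randomization preserving all row and column sums, 999 permutations by
default), top-1% (L1) hotspot delineation with inclusive tie handling,
5-class map binning with protected-area (Natura 2000 style) overlap
accounting, and a crosswalk from the diversity facets to the 11 relevant
CICES ecosystem-service classes.

Because national occurrence databases of this kind are not openly
deposited, the package ships a synthetic-data generator
(`spatdiv.synth`) that emulates the structure of such a study — a
right-skewed range-size distribution dominated by narrow endemics,
spreading-dye spatial cohesion, an ultrametric dated phylogeny, partial
trait coverage, 13 floristic regions and plantable endemism centers with
exported ground truth — so the entire pipeline is testable end to end.

## Worked example

```python
import dendropy
from spatdiv import (OccurrenceMatrix, Phylogeny, weighted_endemism,
                     corrected_weighted_endemism, faith_pd,
                     phylogenetic_endemism)

occ = OccurrenceMatrix.from_records(
    [("A", "c1"), ("B", "c1"), ("B", "c2"), ("C", "c2")]
)
tree = Phylogeny(dendropy.Tree.get(data="((A:1,B:1):1,C:2);",
                                   schema="newick"))
print(weighted_endemism(occ).values)            # {'c1': 1.5, 'c2': 1.5}
print(corrected_weighted_endemism(occ).values)  # {'c1': 0.75, 'c2': 0.75}
print(faith_pd(occ, tree).values)               # {'c1': 3.0, 'c2': 4.0}
print(phylogenetic_endemism(occ, tree).values)  # {'c1': 2.0, 'c2': 3.0}
```

Cell c1 holds A (endemic, r=1) and B (r=2), so WE = 1/1 + 1/2 = 1.5 and
CWE = 1.5/2 = 0.75. Its PD sums the branches to A, B and their stem
(1+1+1 = 3); its PE divides each branch by its cell range
(1/1 + 1/2 + 1/2 = 2). Summed over all cells, WE recovers the taxon count
(3) and PE the total tree length (5) — conservation identities the test
suite checks at 1e-9 on random data.

## The analysis

`analysis/01…06` run the pipeline as a narrative on one synthetic flora
(600 taxa, 30 × 30 grid, seed fixed in `analysis/common.py`), writing
tables under `results/`:

```sh
python analysis/01_simulate_dataset.py   # data: occ/tree/traits/regions/pa
python analysis/02_taxonomic_endemism.py # SR, WE, CWE + curveball null
python analysis/03_phylogenetic_structure.py  # PD, PE, PD_SES classes
python analysis/04_trait_diversity.py    # six trait surfaces + regions
python analysis/05_hotspots_protection.py# L1 hotspots, 5-class PA overlap
python analysis/06_ecosystem_services.py # CICES relevance per cell
```

Step 02, for example, prints

```
mean cell richness 8.07, max 18
sum of WE over cells = 600.000000000 (taxon count 600; identity holds to 0.0e+00)
CWE defined on 899 cells, range 0.008-0.521
CWE null (199 permutations): 18 cells significantly high, 17 significantly low of 899 tested
```

i.e. the conservation identity holds exactly and, on this cohesive but
unplanted flora, about 4% of cells deviate significantly from the
fixed-margin null in either direction.

The same stages are scriptable on real inputs via the `spatdiv` CLI
(`spatdiv simulate|metrics|nulls|functional|hotspots|overlap|es|run-all`);
`run-all` writes a manifest with config hash, per-stage sub-seeds and
output checksums so a re-run can be verified identical.

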