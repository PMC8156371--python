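"""Quantified validation experiments at fixed study conditions.

Each runner regenerates its synthetic inputs from a seed, executes the
pipeline's estimators, and measures one property end to end:

* conservation identities (sum_c WE_c = S; sum_c PE_c = total tree length);
* agreement of the vectorised PD/PE with a naive per-cell branch
  enumeration that walks the dendropy tree directly;
* collapse of the phylogenetic metrics onto the taxonomic ones on star
  trees (PE = WE, PD = SR with unit pendant branches);
* calibration of the CWE permutation null and of PD_SES on exchangeable
  data generated by the respective null models;
* recovery of a planted endemism center by the L1 hotspot set and by the
  CWE significance test.

Problem sizes are the package's reference conditions and are deliberately
frozen here so tests and the acceptance runner measure the same thing.
"""

from __future__ import annotations

import numpy as np

from .datamodel import OccurrenceMatrix, Phylogeny
from .phylo import faith_pd, pd_ses, phylogenetic_endemism
from .seeding import derive_seed
from .synth import (
    PlantedCenter,
    ScenarioConfig,
    simulate_ranges,
    simulate_tree,
    taxon_names,
)
from .taxonomic import (
    corrected_weighted_endemism,
    cwe_significance,
    species_richness,
    weighted_endemism,
)
from .hotspots import hotspot_l1

import dendropy


# ---------------------------------------------------------------------------
# independent oracle

def naive_pd_pe(occ: OccurrenceMatrix, tree: Phylogeny):
    """Brute-force per-cell PD and PE by direct branch enumeration.

    For every cell, every branch of the dendropy tree is tested for a
    nonempty intersection between its descendant tip set and the cell's
    taxa.  Quadratic and slow on purpose: this is the oracle the fast
    branch-matrix implementation is checked against, sharing none of its
    code path.
    """
    branches = []
    for node in tree.tree.preorder_node_iter():
        if node.edge.length is None:
            continue
        tips = {leaf.taxon.label for leaf in node.leaf_iter()}
        branches.append((float(node.edge.length), tips))
    pd_vals, pe_vals = {}, {}
    cell_taxa = {c: set(occ.taxa_of_cell(c)) for c in occ.cells}
    for length, tips in branches:
        rng_b = sum(1 for c in occ.cells if tips & cell_taxa[c])
        for c in occ.cells:
            if tips & cell_taxa[c]:
                pd_vals[c] = pd_vals.get(c, 0.0) + length
                pe_vals[c] = pe_vals.get(c, 0.0) + length / rng_b
    return pd_vals, pe_vals


# ---------------------------------------------------------------------------
# random instances

def _random_instance(rng: np.random.Generator, max_taxa=200, max_cells=400,
                     min_taxa=5):
    n_taxa = int(rng.integers(min_taxa, max_taxa + 1))
    rows = int(rng.integers(2, 21))
    cols = int(rng.integers(2, max(3, max_cells // rows + 1)))
    cols = min(cols, max_cells // rows)
    cols = max(cols, 2)
    config = ScenarioConfig(
        seed=int(rng.integers(2**31)),
        n_taxa=n_taxa,
        grid_rows=rows,
        grid_cols=cols,
        endemic_fraction=float(rng.uniform(0.2, 0.8)),
        logseries_p=0.95,
        cohesion=float(rng.uniform(0.0, 1.0)),
    )
    occ, _ = simulate_ranges(config)
    tree = simulate_tree(config)
    return occ, tree


def conservation_check(n_instances: int = 100, seed: int = 0) -> dict:
    """Max deviation of the WE and PE conservation identities.

    On every instance sum_c WE_c must equal the taxon count S and
    sum_c PE_c the total tree length.
    """
    rng = np.random.default_rng(derive_seed(seed, "conservation"))
    max_we = 0.0
    max_pe = 0.0
    for _ in range(n_instances):
        occ, tree = _random_instance(rng)
        we = weighted_endemism(occ)
        max_we = max(max_we, abs(we.defined_values().sum() - occ.n_taxa))
        pe = phylogenetic_endemism(occ, tree)
        max_pe = max(
            max_pe, abs(pe.defined_values().sum() - tree.total_length())
        )
    return {"max_we_error": max_we, "max_pe_error": max_pe,
            "n_instances": n_instances}


def oracle_check(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |fast - brute force| over PD and PE on small random instances."""
    rng = np.random.default_rng(derive_seed(seed, "oracle"))
    worst = 0.0
    for _ in range(n_instances):
        occ, tree = _random_instance(
            rng, max_taxa=40, max_cells=30, min_taxa=4
        )
        pd_fast = faith_pd(occ, tree)
        pe_fast = phylogenetic_endemism(occ, tree)
        pd_ref, pe_ref = naive_pd_pe(occ, tree)
        for c in pd_fast.defined_cells():
            worst = max(worst, abs(pd_fast.values[c] - pd_ref.get(c, 0.0)))
            worst = max(worst, abs(pe_fast.values[c] - pe_ref.get(c, 0.0)))
    return {"max_abs_diff": worst, "n_instances": n_instances}


def star_tree_check(n_instances: int = 20, seed: int = 0) -> dict:
    """PE = WE and PD = SR on unit-branch star phylogenies."""
    rng = np.random.default_rng(derive_seed(seed, "star"))
    max_pe_we = 0.0
    max_pd_sr = 0.0
    for _ in range(n_instances):
        n_taxa = int(rng.integers(5, 40))
        names = taxon_names(n_taxa)
        newick = "(" + ",".join(f"{t}:1" for t in names) + ");"
        tree = Phylogeny(dendropy.Tree.get(data=newick, schema="newick"))
        n_cells = int(rng.integers(3, 25))
        cells = [f"c{i:03d}" for i in range(n_cells)]
        X = rng.random((n_cells, n_taxa)) < 0.3
        X[rng.integers(n_cells, size=n_taxa), np.arange(n_taxa)] = True
        occ = OccurrenceMatrix(names, cells, X)
        we, sr = weighted_endemism(occ), species_richness(occ)
        pe, pd_ = phylogenetic_endemism(occ, tree), faith_pd(occ, tree)
        for c in pe.defined_cells():
            max_pe_we = max(max_pe_we, abs(pe.values[c] - we.values[c]))
            max_pd_sr = max(max_pd_sr, abs(pd_.values[c] - sr.values[c]))
    return {"max_pe_we_diff": max_pe_we, "max_pd_sr_diff": max_pd_sr,
            "n_instances": n_instances}


# ---------------------------------------------------------------------------
# null calibration

#: Exchangeable scenario for CWE null calibration: uniform random ranges
#: (cohesion 0), no planting, log-series range sizes.
def _calibration_config(seed: int) -> ScenarioConfig:
    return ScenarioConfig(
        seed=seed, n_taxa=100, grid_rows=10, grid_cols=10,
        endemic_fraction=0.0, logseries_p=0.95, cohesion=0.0,
    )


def cwe_null_calibration(n_matrices: int = 200, n_perm: int = 199,
                         seed: int = 0, algorithm: str = "curveball") -> dict:
    """Pooled rejection rate of the CWE permutation test on null data.

    Every matrix is exchangeable under the fixed-margin null by
    construction, so the fraction of defined cells with p <= 0.05 should
    sit near the nominal level (slightly below it, because ties are
    counted conservatively).
    """
    rng = np.random.default_rng(derive_seed(seed, "cwe_calibration"))
    n_sig = 0
    n_defined = 0
    for _ in range(n_matrices):
        config = _calibration_config(int(rng.integers(2**31)))
        occ, _ = simulate_ranges(config)
        ens = cwe_significance(
            occ, n_perm=n_perm, algorithm=algorithm,
            seed=int(rng.integers(2**31)),
        )
        pvals = np.array(list(ens.p_value.values()))
        n_sig += int((pvals <= 0.05).sum())
        n_defined += len(pvals)
    return {
        "rejection_rate": n_sig / n_defined,
        "n_cells": n_defined,
        "n_matrices": n_matrices,
        "n_perm": n_perm,
    }


def pdses_calibration(n_cells: int = 2000, n_perm: int = 199,
                      seed: int = 0, n_tips: int = 150) -> dict:
    """Mean and sd of PD_SES over cells assembled BY the null model.

    Cells draw their taxa uniformly at fixed richness — exactly the
    uniform_tip_draw null — so the SES distribution should have mean ~0
    and sd ~1.
    """
    rng = np.random.default_rng(derive_seed(seed, "pdses_calibration"))
    config = ScenarioConfig(seed=int(rng.integers(2**31)), n_taxa=n_tips)
    tree = simulate_tree(config)
    names = taxon_names(n_tips)
    cells = [f"c{i:05d}" for i in range(n_cells)]
    X = np.zeros((n_cells, n_tips), dtype=bool)
    richness = rng.integers(2, 51, size=n_cells)
    for i, k in enumerate(richness):
        X[i, rng.choice(n_tips, size=int(k), replace=False)] = True
    occ = OccurrenceMatrix(names, cells, X)
    ens = pd_ses(
        occ, tree, n_perm=n_perm, null_model="uniform_tip_draw",
        seed=int(rng.integers(2**31)),
    )
    ses = np.array(list(ens.ses.values()))
    return {
        "mean": float(ses.mean()),
        "sd": float(ses.std(ddof=1)),
        "n_cells": len(ses),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# planted-center recovery

#: Recovery scenario: 20 single-cell endemics in a two-cell block on a
#: 20 x 20 grid over a widespread background flora (ranges >= 3 cells).
def _recovery_config(seed: int) -> ScenarioConfig:
    return ScenarioConfig(
        seed=seed, n_taxa=170, grid_rows=20, grid_cols=20,
        endemic_fraction=0.0, logseries_p=0.95, cohesion=0.8,
        background_range_min=3,
        planted=PlantedCenter(
            block=[(10, 10), (10, 11)], n_endemics=20,
            range_min=1, range_max=1,
        ),
    )


def planted_recovery(n_replicates: int = 100, n_perm: int = 199,
                     seed: int = 0, level: float = 0.99) -> dict:
    """Recovery of a planted endemism center across replicate datasets.

    Counts the replicates in which both block cells (a) enter the L1 CWE
    hotspot set and (b) are classified significantly high by the
    permutation test at alpha = 0.05.
    """
    rng = np.random.default_rng(derive_seed(seed, "recovery"))
    n_l1 = 0
    n_sig = 0
    for _ in range(n_replicates):
        config = _recovery_config(int(rng.integers(2**31)))
        occ, truth = simulate_ranges(config)
        planted_cells = truth["planted_cells"]
        cwe = corrected_weighted_endemism(occ)
        hs = hotspot_l1(cwe, level=level)
        if all(c in hs.members for c in planted_cells):
            n_l1 += 1
        ens = cwe_significance(
            occ, n_perm=n_perm, algorithm="curveball",
            seed=int(rng.integers(2**31)),
        )
        sig = ens.significance(alpha=0.05)
        if all(sig.get(c) == "high" for c in planted_cells):
            n_sig += 1
    return {
        "n_replicates": n_replicates,
        "n_l1_recovered": n_l1,
        "n_significant_recovered": n_sig,
        "n_perm": n_perm,
    }
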