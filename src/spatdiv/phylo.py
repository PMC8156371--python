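"""Faith's PD, phylogenetic endemism and standardized-effect-size PD.

All three metrics are computed from one branch-by-taxon incidence table:
branch b (length L_b) is *present* in cell c iff any tip descending from b
occurs in c, and its range R_b is the number of such cells.  Then

* PD_c = sum of L_b over branches present in c (root-inclusive: every
  branch on the paths from the cell's tips up to the root counts, so
  single-taxon cells have a well-defined PD and a cell holding every tip
  recovers the total tree length);
* PE_c = sum of L_b / R_b — each branch spreads its length over its range,
  hence sum_c PE_c equals the total tree length;
* PD_SES,c = (PD_c - mean PD_null,c) / sd PD_null,c under a fixed-richness
  null, with |SES| >= 1.96 read as significant phylogenetic overdispersion
  (+) or clustering (-).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import MetricSurface, NullEnsemble, OccurrenceMatrix, Phylogeny
from .errors import AlignmentError, ConfigError

log = logging.getLogger("spatdiv")


def branch_taxon_matrix(tree: Phylogeny, taxa):
    """Branch lengths and branch x taxon descendant-tip incidence.

    Returns ``(lengths, incidence)`` with ``lengths`` of shape
    ``(n_branches,)`` and boolean ``incidence`` of shape
    ``(n_branches, len(taxa))``.  Every edge with a recorded length is a
    branch, including a root edge when the Newick carries one.
    """
    index = {t: i for i, t in enumerate(taxa)}
    tips = set(tree.tip_labels())
    extra = tips - set(taxa)
    if extra:
        raise AlignmentError(
            f"tree tips absent from the taxon list (prune first): "
            f"{sorted(extra)[:5]}"
        )
    masks = {}
    lengths, rows = [], []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(len(taxa), dtype=bool)
            mask[index[node.taxon.label]] = True
        else:
            mask = np.zeros(len(taxa), dtype=bool)
            for child in node.child_nodes():
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.edge.length is not None:
            lengths.append(float(node.edge.length))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)


def branch_range_table(occ: OccurrenceMatrix, tree: Phylogeny) -> pd.DataFrame:
    """Per-branch length L_b and range R_b (cells holding a descendant tip)."""
    lengths, inc = branch_taxon_matrix(tree, occ.taxa)
    present = inc @ occ.presence.T > 0          # (n_branches, n_cells)
    return pd.DataFrame(
        {"length": lengths, "range": present.sum(axis=1).astype(int)}
    )


def _branch_cell_presence(occ, tree):
    lengths, inc = branch_taxon_matrix(tree, occ.taxa)
    present = inc @ occ.presence.T > 0          # (n_branches, n_cells)
    return lengths, present


def faith_pd(occ: OccurrenceMatrix, tree: Phylogeny) -> MetricSurface:
    """Faith's PD per cell; undefined for empty cells."""
    lengths, present = _branch_cell_presence(occ, tree)
    pd_vals = lengths @ present
    sr = occ.cell_richness()
    values = {
        c: float(v) for c, v, k in zip(occ.cells, pd_vals, sr) if k > 0
    }
    return MetricSurface("PD", list(occ.cells), values)


def phylogenetic_endemism(occ: OccurrenceMatrix, tree: Phylogeny) -> MetricSurface:
    """PE_c = sum over branches present in c of L_b / R_b."""
    lengths, present = _branch_cell_presence(occ, tree)
    ranges = present.sum(axis=1).astype(float)
    nonzero = ranges > 0
    pe_vals = (lengths[nonzero] / ranges[nonzero]) @ present[nonzero]
    sr = occ.cell_richness()
    values = {
        c: float(v) for c, v, k in zip(occ.cells, pe_vals, sr) if k > 0
    }
    return MetricSurface("PE", list(occ.cells), values)


def pd_ses(
    occ: OccurrenceMatrix,
    tree: Phylogeny,
    n_perm: int = 999,
    null_model: str = "uniform_tip_draw",
    seed: int | None = None,
) -> NullEnsemble:
    """Standardized effect size of PD under a fixed-richness null.

    ``uniform_tip_draw`` (default) draws, independently for every cell,
    ``n_perm`` random sets of SR_c tips uniformly without replacement from
    the tip pool — the classic "richness" null whose moments SES tools
    compute; here they are Monte-Carlo estimates.  ``tip_label_shuffle``
    permutes the tip labels of the tree once per replicate, preserving the
    co-occurrence structure of the matrix.

    Cells whose null does not vary (sd = 0, e.g. a cell holding every tip)
    get an undefined SES and are reported, never dropped silently.
    """
    if n_perm < 2:
        raise ConfigError("n_perm must be >= 2 for an SES")
    if seed is None:
        raise ConfigError("a seed is required for reproducibility")
    if null_model not in ("uniform_tip_draw", "tip_label_shuffle"):
        raise ConfigError(f"unknown null model '{null_model}'")

    lengths, inc = branch_taxon_matrix(tree, occ.taxa)
    present = inc @ occ.presence.T > 0
    pd_obs = lengths @ present
    sr = occ.cell_richness()
    n_taxa = occ.n_taxa
    rng = np.random.default_rng(seed)
    inc_f = inc.astype(np.float32)

    null = np.empty((n_perm, occ.n_cells))
    if null_model == "uniform_tip_draw":
        for idx in range(occ.n_cells):
            k = int(sr[idx])
            if k == 0:
                null[:, idx] = np.nan
                continue
            # n_perm random k-subsets of the tip pool, one per column
            order = np.argsort(rng.random((n_perm, n_taxa)), axis=1)[:, :k]
            S = np.zeros((n_taxa, n_perm), dtype=np.float32)
            S[order.T, np.arange(n_perm)[None, :]] = 1.0
            pres = inc_f @ S > 0
            null[:, idx] = lengths @ pres
    else:  # tip_label_shuffle
        for r in range(n_perm):
            perm = rng.permutation(n_taxa)
            pres = inc[:, perm] @ occ.presence.T > 0
            null[r] = lengths @ pres

    observed, null_mean, null_sd, rank, p_value, ses = {}, {}, {}, {}, {}, {}
    n_undefined = 0
    for idx, cell in enumerate(occ.cells):
        if sr[idx] == 0:
            continue
        col = null[:, idx]
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        p_high = (1 + int((col >= pd_obs[idx]).sum())) / (1 + n_perm)
        p_low = (1 + int((col <= pd_obs[idx]).sum())) / (1 + n_perm)
        observed[cell] = float(pd_obs[idx])
        null_mean[cell] = mean
        null_sd[cell] = sd
        rank[cell] = int((col < pd_obs[idx]).sum())
        p_value[cell] = min(1.0, 2.0 * min(p_low, p_high))
        if sd > 0:
            ses[cell] = (float(pd_obs[idx]) - mean) / sd
        else:
            n_undefined += 1
    if n_undefined:
        log.warning(
            "PD_SES undefined for %d cells whose null PD does not vary",
            n_undefined,
        )
    return NullEnsemble(
        metric="PD", cells=list(occ.cells), observed=observed,
        null_mean=null_mean, null_sd=null_sd, rank=rank, p_value=p_value,
        n_permutations=n_perm, algorithm=null_model, seed=seed, ses=ses,
    )


def ses_surface(ensemble: NullEnsemble) -> MetricSurface:
    """Extract the SES values of a PD ensemble as a surface."""
    return MetricSurface("PD_SES", list(ensemble.cells), dict(ensemble.ses))


def classify_pdses(ses: MetricSurface, threshold: float = 1.96) -> dict[str, str]:
    """Classify each cell by its PD_SES value.

    Boundary-inclusive: SES >= threshold is 'overdispersed', SES <=
    -threshold is 'clustered', anything strictly between is
    'nonsignificant'; cells without an SES are 'undefined'.
    """
    out = {}
    for cell in ses.cells:
        if cell not in ses.values:
            out[cell] = "undefined"
        elif ses.values[cell] >= threshold:
            out[cell] = "overdispersed"
        elif ses.values[cell] <= -threshold:
            out[cell] = "clustered"
        else:
            out[cell] = "nonsignificant"
    return out
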