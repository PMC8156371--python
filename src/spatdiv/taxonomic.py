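"""Species richness, weighted endemism and its permutation-null test.

Per cell c with taxa s of range size r_s (occupied-cell count):

* SR_c  = number of taxa present,
* WE_c  = sum over present taxa of 1/r_s (range-size rarity),
* CWE_c = WE_c / SR_c, the mean inverse range size — endemism corrected for
  richness; undefined at SR_c = 0.

WE satisfies the conservation identity sum_c WE_c = S (each taxon spreads a
total weight of exactly 1 over its range), which the tests exploit.

The significance of CWE is assessed against a permutation null.  The default
``curveball`` algorithm randomizes the presence/absence matrix while keeping
every taxon range and every cell richness fixed, isolating the *identity*
composition of cells; ``tip_shuffle`` keeps only cell richness, redrawing
each cell's taxa uniformly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import MetricSurface, NullEnsemble, OccurrenceMatrix
from .errors import ConfigError, ValidationError

log = logging.getLogger("spatdiv")


def species_richness(occ: OccurrenceMatrix) -> MetricSurface:
    """Per-cell taxon count SR_c (0 for empty cells; always defined)."""
    sr = occ.cell_richness()
    return MetricSurface(
        "SR", list(occ.cells), {c: float(v) for c, v in zip(occ.cells, sr)}
    )


def weighted_endemism(occ: OccurrenceMatrix) -> MetricSurface:
    """WE_c = sum over taxa present in c of 1 / r_s."""
    ranges = occ.range_sizes().astype(float)
    if (ranges < 1).any():
        raise ValidationError("every taxon must occupy at least one cell")
    we = occ.presence @ (1.0 / ranges)
    return MetricSurface(
        "WE", list(occ.cells), {c: float(v) for c, v in zip(occ.cells, we)}
    )


def corrected_weighted_endemism(occ: OccurrenceMatrix) -> MetricSurface:
    """CWE_c = WE_c / SR_c; undefined where SR_c = 0."""
    sr = occ.cell_richness()
    we = weighted_endemism(occ)
    values = {
        c: we.values[c] / float(s)
        for c, s in zip(occ.cells, sr) if s > 0
    }
    return MetricSurface("CWE", list(occ.cells), values)


# ---------------------------------------------------------------------------
# curveball machinery

def _to_sets(occ: OccurrenceMatrix) -> list[set]:
    """Row representation: taxon index -> set of occupied cell indices."""
    return [set(np.flatnonzero(occ.presence[:, j]).tolist())
            for j in range(occ.n_taxa)]


def curveball_trades(rows: list[set], n_trades: int,
                     rng: np.random.Generator) -> None:
    """Perform ``n_trades`` curveball trade attempts in place.

    A trade picks two distinct taxa and reallocates the cells unique to
    each uniformly at random between them, preserving every row sum (taxon
    range) and column sum (cell richness) exactly.  Only the smaller side
    of the exchangeable pool is sampled (a partial Fisher-Yates over
    buffered uniforms), which is equivalent to shuffling the whole pool.
    """
    n = len(rows)
    pair_buf = rng.integers(0, n, size=max(4096, 2 * n_trades)).tolist()
    pp = 0
    flen = 65536
    fbuf = rng.random(flen).tolist()
    fp = 0
    done = 0
    while done < n_trades:
        if pp + 2 > len(pair_buf):
            pair_buf = rng.integers(0, n, size=4096).tolist()
            pp = 0
        i = pair_buf[pp]
        j = pair_buf[pp + 1]
        pp += 2
        if i == j:
            continue
        done += 1
        a, b = rows[i], rows[j]
        a_only = [x for x in a if x not in b]
        if not a_only:
            continue
        b_only = [x for x in b if x not in a]
        if not b_only:
            continue
        pool = a_only + b_only
        m = len(pool)
        ka = len(a_only)
        s = ka if ka <= m - ka else m - ka
        if fp + s > flen:
            fbuf = rng.random(max(flen, s)).tolist()
            fp = 0
        for t in range(s):
            r = t + int(fbuf[fp] * (m - t))
            fp += 1
            pool[t], pool[r] = pool[r], pool[t]
        shared = a & b
        if ka <= m - ka:
            rows[i] = shared.union(pool[:s])
            rows[j] = shared.union(pool[s:])
        else:
            rows[j] = shared.union(pool[:s])
            rows[i] = shared.union(pool[s:])


def _we_from_rows(rows: list[set], inv_ranges, n_cells: int) -> np.ndarray:
    we = [0.0] * n_cells
    for cells, w in zip(rows, inv_ranges):
        for c in cells:
            we[c] += w
    return np.asarray(we)


def _tip_shuffle_matrix(sr, n_taxa, rng: np.random.Generator) -> list[set]:
    """Fixed-richness redraw: each cell gets SR_c taxa uniformly at random."""
    rows = [set() for _ in range(n_taxa)]
    for c, k in enumerate(sr):
        if k == 0:
            continue
        for t in rng.choice(n_taxa, size=int(k), replace=False):
            rows[int(t)].add(c)
    return rows


def cwe_significance(
    occ: OccurrenceMatrix,
    n_perm: int = 999,
    algorithm: str = "curveball",
    seed: int | None = None,
    burn_in_factor: int = 5,
    trades_per_step: int | None = None,
    check_margins: bool = False,
) -> NullEnsemble:
    """Permutation-null test of per-cell CWE.

    Parameters
    ----------
    n_perm
        Number of null replicates (999 matches the study protocol; the
        one-tailed p floor is 1/(n_perm+1)).
    algorithm
        ``curveball`` (fixed row and column sums; the chain burns in for
        ``burn_in_factor`` x presences trades and advances
        ``trades_per_step`` trades — default: the presence count — between
        replicates) or ``tip_shuffle`` (richness-only null; ranges are
        recomputed from each redrawn matrix).
    seed
        Mandatory; identical seed and inputs give an identical ensemble.
    check_margins
        Assert row/column-sum preservation on every curveball replicate.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if seed is None:
        raise ConfigError("a seed is required for reproducibility")
    if algorithm not in ("curveball", "tip_shuffle"):
        raise ConfigError(f"unknown null algorithm '{algorithm}'")

    sr = occ.cell_richness()
    ranges = occ.range_sizes().astype(float)
    inv_ranges = 1.0 / ranges
    defined = sr > 0
    obs_we = occ.presence @ inv_ranges
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_cwe = np.where(defined, obs_we / np.maximum(sr, 1), np.nan)

    n_cells = occ.n_cells
    count_ge = np.zeros(n_cells, dtype=np.int64)
    count_le = np.zeros(n_cells, dtype=np.int64)
    count_lt = np.zeros(n_cells, dtype=np.int64)
    s1 = np.zeros(n_cells)
    s2 = np.zeros(n_cells)

    if algorithm == "curveball":
        rng = np.random.default_rng(seed)
        rows = _to_sets(occ)
        n_pres = occ.n_presences
        step = trades_per_step if trades_per_step is not None else n_pres
        curveball_trades(rows, burn_in_factor * n_pres, rng)
        sr_f = np.maximum(sr, 1).astype(float)
        for _ in range(n_perm):
            curveball_trades(rows, step, rng)
            if check_margins:
                _assert_margins(rows, ranges, sr, n_cells)
            null_we = _we_from_rows(rows, inv_ranges, n_cells)
            null_cwe = null_we / sr_f
            _accumulate(null_cwe, obs_cwe, defined,
                        count_ge, count_le, count_lt, s1, s2)
    else:  # tip_shuffle
        rng = np.random.default_rng(seed)
        sr_f = np.maximum(sr, 1).astype(float)
        for _ in range(n_perm):
            rows = _tip_shuffle_matrix(sr, occ.n_taxa, rng)
            null_ranges = np.array([len(s) for s in rows], dtype=float)
            inv_nr = np.where(null_ranges > 0, 1.0 / np.maximum(null_ranges, 1), 0.0)
            null_we = _we_from_rows(rows, inv_nr, n_cells)
            null_cwe = null_we / sr_f
            _accumulate(null_cwe, obs_cwe, defined,
                        count_ge, count_le, count_lt, s1, s2)

    observed, null_mean, null_sd, rank, p_value = {}, {}, {}, {}, {}
    for idx, cell in enumerate(occ.cells):
        if not defined[idx]:
            continue
        mean = s1[idx] / n_perm
        var = max(s2[idx] / n_perm - mean * mean, 0.0)
        p_high = (1 + count_ge[idx]) / (1 + n_perm)
        p_low = (1 + count_le[idx]) / (1 + n_perm)
        observed[cell] = float(obs_cwe[idx])
        null_mean[cell] = float(mean)
        null_sd[cell] = float(np.sqrt(var))
        rank[cell] = int(count_lt[idx])
        p_value[cell] = float(min(1.0, 2.0 * min(p_low, p_high)))

    log.info(
        "CWE null (%s, n_perm=%d, seed=%s): %d/%d cells defined",
        algorithm, n_perm, seed, len(p_value), n_cells,
    )
    return NullEnsemble(
        metric="CWE", cells=list(occ.cells), observed=observed,
        null_mean=null_mean, null_sd=null_sd, rank=rank, p_value=p_value,
        n_permutations=n_perm, algorithm=algorithm, seed=seed,
    )


def _accumulate(null_v, obs_v, defined, count_ge, count_le, count_lt, s1, s2):
    d = defined
    count_ge[d] += null_v[d] >= obs_v[d]
    count_le[d] += null_v[d] <= obs_v[d]
    count_lt[d] += null_v[d] < obs_v[d]
    s1[d] += null_v[d]
    s2[d] += null_v[d] ** 2


def _assert_margins(rows, ranges, sr, n_cells):
    got_rows = np.array([len(s) for s in rows], dtype=float)
    if not np.array_equal(got_rows, ranges):
        raise AssertionError("curveball altered a taxon range")
    col = np.zeros(n_cells, dtype=int)
    for s in rows:
        for c in s:
            col[c] += 1
    if not np.array_equal(col, sr):
        raise AssertionError("curveball altered a cell richness")


# ---------------------------------------------------------------------------
# regional occupancy

def region_occupancy(taxon_regions: dict, vocabulary,
                     endemic_taxa=None) -> tuple[pd.DataFrame, dict]:
    """Regional occupancy summary from taxon -> {region labels}.

    Returns a per-region table (proportion of taxa present; proportion of
    single-region taxa found there) plus overall single-region proportions,
    for all taxa and for a flagged endemic subset.
    """
    vocab = set(vocabulary)
    for taxon, regions in taxon_regions.items():
        bad = set(regions) - vocab
        if bad:
            raise ValidationError(
                f"taxon {taxon} has unknown region labels {sorted(bad)}"
            )
    n = len(taxon_regions)
    if n == 0:
        raise ValidationError("no taxa with region assignments")
    single = {t for t, r in taxon_regions.items() if len(r) == 1}
    endemic_taxa = set(endemic_taxa) if endemic_taxa is not None else set()
    rows = []
    for region in vocabulary:
        present = [t for t, r in taxon_regions.items() if region in r]
        single_here = [t for t in present if t in single]
        rows.append(
            {
                "region": region,
                "prop_taxa": len(present) / n,
                "prop_single_region": len(single_here) / n,
            }
        )
    summary = {
        "n_taxa": n,
        "single_region_proportion": len(single) / n,
        "endemic_single_region_proportion": (
            len(single & endemic_taxa) / len(endemic_taxa)
            if endemic_taxa else float("nan")
        ),
    }
    return pd.DataFrame(rows), summary
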