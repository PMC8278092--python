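"""Gene-set enrichment.

Two flavours: hypergeometric over-representation of a query gene list
against GMT sets (the classic pathway-annotation test), and preranked
GSEA — a weighted Kolmogorov-Smirnov running-sum with weight |score|^1,
a gene-label permutation null, NES = ES / mean(|null ES| of the same
sign) and an empirical p-value.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet
from .diffexpr import bh_adjust

HYPER_COLUMNS = ["set_id", "n_universe", "n_set", "n_query", "n_overlap",
                 "pvalue", "padj"]
GSEA_COLUMNS = ["set_id", "n_genes", "es", "nes", "pvalue"]


def hypergeom_enrich(query, universe, gmt) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` within ``universe``.

    Query genes outside the universe are dropped with a warning; gene sets
    are intersected with the universe before testing.  Rows are BH-adjusted
    across sets and sorted by adjusted p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"dropping {len(stray)} query gene(s) outside the "
                      f"universe: {sorted(stray)[:5]}", stacklevel=2)
        query &= universe
    M, n_query = len(universe), len(query)
    rows = []
    for gs in gmt:
        members = set(gs.genes) & universe
        k = len(members & query)
        # P(X >= k) with X ~ Hypergeom(M, |set|, |query|)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_query))
        rows.append({"set_id": gs.set_id, "n_universe": M,
                     "n_set": len(members), "n_query": n_query,
                     "n_overlap": k, "pvalue": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=HYPER_COLUMNS[:-1])
    table["padj"] = bh_adjust(table["pvalue"].to_numpy()) if len(table) else []
    return table.sort_values(["padj", "pvalue", "set_id"], ignore_index=True)


def rank_genes(ranked) -> pd.Series:
    """Normalize a (gene, score) list / Series into a descending ranking.

    Ties in score break by gene id (lexicographic) for reproducibility.
    Duplicate genes or non-finite scores raise.
    """
    if isinstance(ranked, pd.Series):
        s = ranked.astype(float)
    else:
        items = list(ranked)
        s = pd.Series([v for _, v in items], index=[g for g, _ in items],
                      dtype=float)
    if s.index.duplicated().any():
        dup = list(s.index[s.index.duplicated()])[:5]
        raise ValueError(f"duplicate genes in ranked list: {dup}")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(ranked: pd.Series, members) -> tuple:
    """Weighted KS enrichment score and the full running sum.

    ``ranked`` must already be sorted (see :func:`rank_genes`).  Hits step
    up by |score| / sum(|score| over hits); misses step down by
    1 / (N - N_hits).  ES is the extremum of the running sum (signed value
    of largest magnitude).  Returns (es, running_sum).
    """
    hit = ranked.index.isin(set(members))
    return _es_from_hits(np.abs(ranked.to_numpy()), hit)


def _es_from_hits(absscores: np.ndarray, hit: np.ndarray) -> tuple:
    nh = int(hit.sum())
    N = hit.size
    if nh == 0 or nh == N:
        raise ValueError("gene set must hit a strict subset of the list")
    w = absscores * hit
    total = w.sum()
    if total == 0:  # all-zero scores: unweighted (equal) hit steps
        steps = np.where(hit, 1.0 / nh, -1.0 / (N - nh))
    else:
        steps = np.where(hit, w / total, -1.0 / (N - nh))
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def gsea_preranked(ranked, gmt, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 1) -> pd.DataFrame:
    """Preranked GSEA over a list of gene sets.

    The null distribution permutes gene labels (equivalently: random hit
    positions of the same set size) with a fixed seed; NES divides ES by
    the mean |null ES| among null draws of the same sign, and p is the
    same-sign empirical tail frequency with a +1 continuity term.  Sets
    with no gene in the list are skipped with a warning.
    """
    s = rank_genes(ranked)
    absscores = np.abs(s.to_numpy())
    N = len(s)
    gene_pos = {g: i for i, g in enumerate(s.index)}
    rng = np.random.default_rng(seed)
    rows = []
    for gs in sorted(gmt, key=lambda g: g.set_id):
        pos = sorted(gene_pos[g] for g in gs.genes if g in gene_pos)
        if len(pos) < min_size or len(pos) == 0:
            warnings.warn(f"gene set {gs.set_id!r} has no gene in the ranked "
                          "list; skipped", stacklevel=2)
            continue
        if len(pos) == N:
            warnings.warn(f"gene set {gs.set_id!r} covers the whole list; "
                          "skipped", stacklevel=2)
            continue
        hit = np.zeros(N, dtype=bool)
        hit[pos] = True
        es, _ = _es_from_hits(absscores, hit)

        nh = len(pos)
        # vectorized permutation null: random hit positions per draw
        idx = np.argsort(rng.random((n_perm, N)), axis=1)[:, :nh]
        hits_mat = np.zeros((n_perm, N), dtype=bool)
        np.put_along_axis(hits_mat, idx, True, axis=1)
        wmat = absscores[None, :] * hits_mat
        totals = wmat.sum(axis=1)
        miss_step = -1.0 / (N - nh)
        safe_tot = np.where(totals > 0, totals, 1.0)
        steps = np.where(hits_mat,
                         np.where(totals[:, None] > 0,
                                  wmat / safe_tot[:, None], 1.0 / nh),
                         miss_step)
        running = np.cumsum(steps, axis=1)
        null_es = np.take_along_axis(
            running, np.argmax(np.abs(running), axis=1)[:, None], axis=1
        ).ravel()

        same = null_es * np.sign(es) > 0 if es != 0 else np.ones_like(null_es, bool)
        denom = np.abs(null_es[same]).mean() if same.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        n_same = int(same.sum())
        n_ge = int((np.abs(null_es[same]) >= abs(es)).sum())
        p = (n_ge + 1) / (n_same + 1)
        rows.append({"set_id": gs.set_id, "n_genes": nh, "es": es,
                     "nes": nes, "pvalue": min(p, 1.0)})
    return pd.DataFrame(rows, columns=GSEA_COLUMNS)
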