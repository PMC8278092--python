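"""ceRNA triplet inference and tripartite network assembly.

A lncRNA and an mRNA form a competing-endogenous-RNA pair through a shared
miRNA when four criteria hold: (1) both miRNA-target arms are supported by
the interaction map (target scan + database whitelist policy); (2) they
share at least one miRNA; (3) both transcripts correlate negatively with
that miRNA; (4) the lncRNA and mRNA correlate positively with each other.
"Negatively/positively correlated" means sign plus a two-sided correlation
p-value below ``alpha_corr`` (default .05).  Correlations are Pearson on
log2(x+1)-transformed abundances across all samples of both groups, and
the candidate universe is restricted to differentially expressed features
of all three classes.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .datatypes import CeRNATriplet, triplets_to_frame  # noqa: F401 (re-export)
from .targets import InteractionMap

log = logging.getLogger(__name__)


def shared_mirnas(lncrna_id: str, mrna_id: str, imap: InteractionMap) -> set:
    """miRNAs targeting both the lncRNA and the mRNA under the map's policy."""
    lnc_m = imap.mirnas_of(lncrna_id)
    mrna_m = imap.mirnas_of(mrna_id)
    if not lnc_m and not mrna_m:
        warnings.warn(
            f"neither {lncrna_id!r} nor {mrna_id!r} is known to the "
            "interaction map", stacklevel=2)
    return lnc_m & mrna_m


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson r and its two-sided p-value (t reference, df = n - 2)."""
    r, p = _corr_rows(x[None, :], y[None, :])
    return float(r[0]), float(p[0])


def _corr_rows(X: np.ndarray, Y: np.ndarray) -> tuple:
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples for correlations")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc * Yc).sum(axis=1) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, np.clip(p, 0.0, 1.0)


def infer_triplets(imap: InteractionMap, expr_all: pd.DataFrame,
                   de_lnc, de_mrna, de_mirna,
                   alpha_corr: float = 0.05,
                   log_transform: bool = True) -> list:
    """Enumerate admissible (lncRNA, miRNA, mRNA) triplets.

    ``expr_all`` holds abundances for every candidate feature (rows) over a
    shared sample set (columns); it is log2(x+1)-transformed internally
    unless ``log_transform`` is False.  The DE sets restrict the candidate
    universe for each node class.
    """
    if expr_all.shape[1] < 3:
        raise ValueError("need at least 3 shared samples for correlations")
    x = expr_all.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    row = {f: i for i, f in enumerate(expr_all.index)}

    lncs = sorted(set(de_lnc) & row.keys())
    mrnas = sorted(set(de_mrna) & row.keys())
    mirs = set(de_mirna) & row.keys()

    triplets = []
    for lnc in lncs:
        lnc_mirs = imap.mirnas_of(lnc) & mirs
        if not lnc_mirs:
            continue
        for mrna in mrnas:
            shared = sorted(lnc_mirs & imap.mirnas_of(mrna))
            if not shared:
                continue
            r_lg, p_lg = correlation_with_p(x[row[lnc]], x[row[mrna]])
            c4 = (r_lg > 0) and (p_lg < alpha_corr)
            if not c4:
                continue
            for mir in shared:
                r_ml, p_ml = correlation_with_p(x[row[mir]], x[row[lnc]])
                r_mg, p_mg = correlation_with_p(x[row[mir]], x[row[mrna]])
                c3 = (r_ml < 0 and p_ml < alpha_corr
                      and r_mg < 0 and p_mg < alpha_corr)
                if not c3:
                    continue
                triplets.append(CeRNATriplet(
                    lncrna_id=lnc, mirna_id=mir, mrna_id=mrna,
                    r_lnc_mrna=r_lg, r_mir_lnc=r_ml, r_mir_mrna=r_mg,
                    p_lnc_mrna=p_lg, p_mir_lnc=p_ml, p_mir_mrna=p_mg,
                    c1_db=True, c2_shared=True, c3_negative=True,
                    c4_positive=True))
    log.info("ceRNA inference: %d triplets from %d lncRNAs x %d mRNAs",
             len(triplets), len(lncs), len(mrnas))
    return triplets


def build_cerna_network(triplets) -> nx.Graph:
    """Deduplicated tripartite network from triplets.

    Nodes carry a ``role`` attribute; edges (lncRNA-miRNA and miRNA-mRNA
    only — competition is via the shared miRNA, so there are never direct
    lncRNA-mRNA edges) carry the number of supporting triplets.  The full
    triplet key list is stored on ``graph.graph["triplets"]``.
    """
    g = nx.Graph()
    keys = sorted({t.key for t in triplets})
    g.graph["triplets"] = keys
    for lnc, mir, mrna in keys:
        g.add_node(lnc, role="lncRNA")
        g.add_node(mir, role="miRNA")
        g.add_node(mrna, role="mRNA")
        for u, v in ((lnc, mir), (mir, mrna)):
            if g.has_edge(u, v):
                g[u][v]["n_triplets"] += 1
            else:
                g.add_edge(u, v, n_triplets=1)
    counts = {r: sum(1 for _, d in g.nodes(data=True) if d["role"] == r)
              for r in ("lncRNA", "miRNA", "mRNA")}
    log.info("ceRNA network: %s nodes, %d edges", counts, g.number_of_edges())
    return g


def extract_anchor_motifs(network: nx.Graph, anchor_id: str,
                          triplets=None) -> list:
    """All 3-node motifs whose mRNA or lncRNA equals ``anchor_id``.

    Operates on the triplet provenance stored in the network (or an
    explicit triplet list, which preserves correlation fields).  Warns and
    returns [] for an absent anchor.
    """
    if anchor_id not in network.nodes:
        warnings.warn(f"anchor {anchor_id!r} not present in the ceRNA network",
                      stacklevel=2)
        return []
    if triplets is not None:
        return [t for t in sorted(triplets, key=lambda t: t.key)
                if anchor_id in (t.lncrna_id, t.mrna_id)]
    return [key for key in network.graph.get("triplets", [])
            if anchor_id in (key[0], key[2])]


def cerna_network_to_frame(g: nx.Graph) -> pd.DataFrame:
    """Edge-list table (u, v, role_u, role_v, n_triplets), sorted."""
    rows = []
    for u, v, data in g.edges(data=True):
        u, v = sorted((u, v))
        rows.append({"u": u, "v": v,
                     "role_u": g.nodes[u]["role"], "role_v": g.nodes[v]["role"],
                     "n_triplets": data["n_triplets"]})
    frame = pd.DataFrame(rows, columns=["u", "v", "role_u", "role_v",
                                        "n_triplets"])
    return frame.sort_values(["u", "v"], ignore_index=True)
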