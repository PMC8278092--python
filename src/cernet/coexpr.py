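"""WGCNA-style lncRNA-PCG co-expression network.

Pearson correlation across samples, soft-thresholded into an unsigned
adjacency a_uv = |r_uv|^beta; beta is picked as the smallest power whose
degree distribution approximates scale-free topology (R^2 of log10 p(k) vs
log10 k over 10 degree bins).  Edges are kept when the adjacency exceeds
the threshold (strictly, default 0.02) and at least one endpoint is a
lncRNA; the correlation sign is carried as edge metadata.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import networkx as nx

log = logging.getLogger(__name__)

DEFAULT_POWER = 6


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between features (rows) across samples (columns).

    Zero-variance features are dropped with a warning (their correlation is
    undefined).  Requires >= 3 samples.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = expr.to_numpy(dtype=float)
    var = x.var(axis=1)
    if (var == 0).any():
        dropped = list(expr.index[var == 0])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}",
            stacklevel=2,
        )
        expr = expr.loc[var > 0]
        x = expr.to_numpy(dtype=float)
    r = np.atleast_2d(np.corrcoef(x))
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=expr.index, columns=expr.index)


def adjacency(corr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |r|^power with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = np.abs(corr.to_numpy(dtype=float)) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_r2(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k regression over degree bins.

    Degrees k are the adjacency row sums, split into ``n_bins`` equal-width
    bins; empty bins are dropped.  Returns 0 when fewer than 3 occupied bins
    remain (no meaningful fit).
    """
    k = np.asarray(adj).sum(axis=0)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    fit = stats_linregress(np.array(xs), np.array(ys))
    return fit


def stats_linregress(x: np.ndarray, y: np.ndarray) -> float:
    # r^2 of the simple linear regression (guard against constant x)
    if np.ptp(x) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_soft_power(corr: pd.DataFrame, candidates=range(1, 21),
                    r2_min: float = 0.8) -> int:
    """Smallest candidate power with scale-free fit R^2 >= ``r2_min``.

    Falls back to the conventional default 6 (with a warning) when no
    candidate qualifies.
    """
    for beta in candidates:
        if scale_free_r2(adjacency(corr, beta)) >= r2_min:
            return int(beta)
    warnings.warn(
        f"no candidate power reached scale-free R^2 >= {r2_min}; "
        f"falling back to {DEFAULT_POWER}", stacklevel=2,
    )
    return DEFAULT_POWER


def build_lncrna_pcg_network(adj: pd.DataFrame, biotypes: pd.Series,
                             threshold: float = 0.02,
                             corr: pd.DataFrame | None = None) -> nx.Graph:
    """Edge (u, v) kept iff adjacency > threshold and u or v is a lncRNA.

    miRNAs are excluded from this network.  ``corr`` (optional) supplies the
    correlation sign stored on each edge.  Unknown biotypes raise.
    """
    ids = list(adj.index)
    bt = pd.Series(biotypes)
    for f in ids:
        if f not in bt.index:
            raise ValueError(f"unknown biotype for feature {f!r}")
        if bt[f] not in ("mRNA", "lncRNA", "miRNA"):
            raise ValueError(f"unknown biotype {bt[f]!r} for feature {f!r}")
    keep = [f for f in ids if bt[f] != "miRNA"]
    a = adj.loc[keep, keep].to_numpy()
    is_lnc = np.array([bt[f] == "lncRNA" for f in keep])

    g = nx.Graph()
    for f in keep:
        g.add_node(f, biotype=bt[f])
    iu, ju = np.triu_indices(len(keep), k=1)
    passing = (a[iu, ju] > threshold) & (is_lnc[iu] | is_lnc[ju])
    signs = None
    if corr is not None:
        c = corr.loc[keep, keep].to_numpy()
        signs = np.sign(c[iu, ju]).astype(int)
    for idx in np.flatnonzero(passing):
        u, v = keep[iu[idx]], keep[ju[idx]]
        attrs = {"weight": float(a[iu[idx], ju[idx]])}
        attrs["sign"] = int(signs[idx]) if signs is not None else 0
        g.add_edge(u, v, **attrs)
    log.info("co-expression network: %d nodes, %d edges (threshold > %g)",
             g.number_of_nodes(), g.number_of_edges(), threshold)
    return g


def extract_subnetwork(network: nx.Graph, node_set) -> nx.Graph:
    """Subnetwork of edges with at least one endpoint in ``node_set``.

    Node set of the result is exactly the endpoints of retained edges; the
    input network is left unmodified.
    """
    node_set = set(node_set)
    if not node_set:
        raise ValueError("node_set must be nonempty")
    if not node_set & set(network.nodes):
        warnings.warn("node_set is disjoint from the network; "
                      "returning an empty network", stacklevel=2)
        return nx.Graph()
    sub = nx.Graph()
    for u, v, data in network.edges(data=True):
        if u in node_set or v in node_set:
            sub.add_node(u, **network.nodes[u])
            sub.add_node(v, **network.nodes[v])
            sub.add_edge(u, v, **data)
    return sub


def network_to_frame(g: nx.Graph) -> pd.DataFrame:
    """Edge-list table (u, v, weight, sign, biotype_u, biotype_v), sorted."""
    rows = []
    for u, v, data in g.edges(data=True):
        u, v = sorted((u, v))
        rows.append({
            "u": u, "v": v,
            "weight": data.get("weight", np.nan),
            "sign": data.get("sign", 0),
            "biotype_u": g.nodes[u].get("biotype", ""),
            "biotype_v": g.nodes[v].get("biotype", ""),
        })
    frame = pd.DataFrame(rows, columns=["u", "v", "weight", "sign",
                                        "biotype_u", "biotype_v"])
    return frame.sort_values(["u", "v"], ignore_index=True)
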