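"""Spearman-thresholded co-occurrence network inference.

An edge connects two variables (per-sample monomial risk factors, the
integrated risk index, and 16S-normalized gene abundances) when their
pairwise Spearman correlation is both strong (|rho| > 0.6 by default,
strict) and significant (p < 0.05, strict).  The absolute value is used so
that strong negative associations also pass the filter; the sign is kept
as an edge attribute.  Modules are communities found by modularity
maximization on |rho| weights; the hub of a module is its most densely
connected node.

Because Spearman depends only on ranks, the network is invariant under any
strictly monotone transform of the input columns.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from . import stats
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

NODE_CATEGORIES = ("RI", "MRG", "ARG", "MGE", "ENV")


def build_network(
    table: pd.DataFrame,
    categories: dict,
    *,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.05,
    max_nondetect_frac: float | None = None,
) -> nx.Graph:
    """Build the co-occurrence graph from a samples x variables table.

    Parameters
    ----------
    table
        Numeric table; every column must appear in ``categories``.
    categories
        Mapping variable -> category label (e.g. RI / MRG / ARG / MGE).
    rho_threshold, p_threshold
        An edge is kept iff |rho| > rho_threshold AND p < p_threshold,
        both strict: a pair at exactly the cutoff is excluded.
    max_nondetect_frac
        Optionally drop variables whose fraction of zeros exceeds this
        value before correlating (off by default; site-wide absences are
        informative and are kept).

    Constant variables cannot be ranked and are excluded with a warning.
    Node attributes: ``category``, ``degree`` (set by this function and
    refreshed by exporters).  Edge attributes: ``rho``, ``p``, ``sign``
    ('+'/'-') and ``weight`` = |rho| (used for community detection).
    """
    num = table.select_dtypes("number")
    untagged = [c for c in num.columns if c not in categories]
    if untagged:
        raise ValidationError(f"variables without a category: {untagged}")
    if len(num) < 4:
        raise ValidationError("need >=4 samples to build a network")
    cols = list(num.columns)
    if max_nondetect_frac is not None:
        keep = [c for c in cols if (num[c] == 0).mean() <= max_nondetect_frac]
        dropped = sorted(set(cols) - set(keep))
        if dropped:
            logger.warning("excluding variables with >%.0f%% non-detects: %s",
                           100 * max_nondetect_frac, dropped)
        cols = keep
    constant = [c for c in cols if num[c].nunique() <= 1]
    if constant:
        logger.warning("excluding constant variables from the network: %s", constant)
        cols = [c for c in cols if c not in constant]

    graph = nx.Graph(rho_threshold=rho_threshold, p_threshold=p_threshold)
    for c in cols:
        graph.add_node(c, category=str(categories[c]))
    corr = stats.spearman_matrix(num[cols])
    for row in corr.itertuples(index=False):
        if pd.isna(row.rho) or pd.isna(row.p):
            continue
        if abs(row.rho) > rho_threshold and row.p < p_threshold:
            graph.add_edge(
                row.var1,
                row.var2,
                rho=float(row.rho),
                p=float(row.p),
                sign="+" if row.rho > 0 else "-",
                weight=abs(float(row.rho)),
            )
    _refresh_degrees(graph)
    return graph


def _refresh_degrees(graph: nx.Graph) -> None:
    for node, deg in graph.degree():
        graph.nodes[node]["degree"] = int(deg)


def detect_modules(graph: nx.Graph, seed: int = 0, *, method: str = "louvain") -> dict:
    """Assign a module id to every node by modularity maximization.

    ``method="louvain"`` runs multi-level (Louvain) modularity optimization
    on |rho| weights, deterministic for a fixed seed and input order;
    ``method="greedy"`` uses deterministic greedy agglomeration (CNM) as a
    seed-free cross-check.  Degree-0 nodes each form their own module.
    Module ids are integers ordered by decreasing module size, ties broken
    by smallest member id; assignments are written to the ``module`` node
    attribute and returned as a dict.
    """
    if method == "louvain":
        communities = nx.community.louvain_communities(
            graph, weight="weight", seed=int(seed)
        )
    elif method == "greedy":
        active = graph.subgraph([n for n, d in graph.degree() if d > 0])
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(active, weight="weight")] \
            if active.number_of_edges() else []
        communities += [{n} for n, d in graph.degree() if d == 0]
    else:
        raise ConfigurationError(f"unknown community method {method!r}")
    communities = sorted(
        (sorted(c, key=str) for c in communities), key=lambda c: (-len(c), str(c[0]))
    )
    assignment = {}
    for mid, members in enumerate(communities):
        for node in members:
            assignment[node] = mid
    nx.set_node_attributes(graph, assignment, "module")
    return assignment


def find_hubs(graph: nx.Graph) -> dict:
    """Pick the hub of every non-singleton module.

    The hub is the node of maximum within-module degree; ties are broken
    by the larger sum of |rho| over within-module edges, then by
    lexicographically smallest node id (tie-break path logged).  Sets the
    boolean ``hub`` node attribute and returns module id -> hub node.
    """
    modules: dict[int, list] = {}
    for node, data in graph.nodes(data=True):
        if "module" not in data:
            raise ValidationError("run detect_modules before find_hubs")
        modules.setdefault(data["module"], []).append(node)
    nx.set_node_attributes(graph, False, "hub")
    hubs = {}
    for mid, members in modules.items():
        if len(members) < 2:
            continue
        member_set = set(members)

        def _score(node):
            within = [
                (nbr, d) for nbr, d in graph[node].items() if nbr in member_set
            ]
            return (len(within), sum(abs(d["rho"]) for _, d in within))

        scored = sorted(members, key=lambda n: (*[-s for s in _score(n)], str(n)))
        best = scored[0]
        if len(scored) > 1 and _score(scored[0])[0] == _score(scored[1])[0]:
            logger.info(
                "module %d: degree tie between %s broken by |rho| sum then id",
                mid, [scored[0], scored[1]],
            )
        hubs[mid] = best
        graph.nodes[best]["hub"] = True
    return hubs


def node_table(graph: nx.Graph) -> pd.DataFrame:
    """Tidy node table (id, category, module, degree, hub)."""
    _refresh_degrees(graph)
    rows = [
        {
            "id": n,
            "category": d.get("category", ""),
            "module": d.get("module", -1),
            "degree": d.get("degree", 0),
            "hub": bool(d.get("hub", False)),
        }
        for n, d in graph.nodes(data=True)
    ]
    return pd.DataFrame(rows).sort_values("id", key=lambda s: s.astype(str)).reset_index(drop=True)


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Tidy edge table (source, target, rho, p, sign)."""
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])
    return df.sort_values(["source", "target"]).reset_index(drop=True)


def export_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML, GEXF or a TSV edge list.

    GraphML/GEXF round-trip all node and edge attributes with types; the
    edge list carries (source, target, rho, p, sign).
    """
    _refresh_degrees(graph)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "gexf":
        nx.write_gexf(graph, path)
    elif format == "edge-list":
        edge_table(graph).to_csv(path, sep="\t", index=False)
    else:
        raise ConfigurationError(
            f"unknown export format {format!r}; use graphml, gexf or edge-list"
        )
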