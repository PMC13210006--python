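"""Module partitioning of the genus-level network and module-nutrient links.

Community detection is agglomerative modularity maximisation (the
fast-greedy / CNM scheme): start from singleton communities and repeatedly
apply the merge with the largest modularity gain, keeping the partition of
maximum Q along the merge sequence. Edges are weighted by |r| — modularity
is defined for non-negative weights, so correlation signs are dropped here
(they are retained on the network itself).

A minimum-module-size rule then merges undersized modules into the
neighbouring module they share the most |r| weight with, which stabilises
the partition against fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureTable, NutrientTable

__all__ = [
    "ModulePartition",
    "ModuleNutrientAssociation",
    "detect_modules",
    "enforce_min_size",
    "module_abundance",
    "module_nutrient_regression",
    "module_nutrient_table",
    "weighted_modularity",
]


def _edge_weight(d: dict) -> float:
    if "r" in d:
        return abs(float(d["r"]))
    return abs(float(d.get("weight", 1.0)))


@dataclass
class ModulePartition:
    """Exhaustive, disjoint assignment of network nodes to modules."""

    assignments: dict  # taxon -> module id
    members: dict  # module id -> sorted member list
    modularity: float
    unassigned: set = field(default_factory=set)  # flagged small isolates

    def __len__(self) -> int:
        return len(self.members)

    def labels_for(self, taxa) -> list:
        return [self.assignments[t] for t in taxa]


def weighted_modularity(g: nx.Graph, communities) -> float:
    """Newman-Girvan Q for a node partition, |r|-weighted.

    Q = sum_c [ W_c/m - (d_c / 2m)^2 ] with W_c the within-community edge
    weight, d_c the community strength and m the total edge weight.
    """
    m = sum(_edge_weight(d) for _, _, d in g.edges(data=True))
    if m == 0:
        return 0.0
    node_comm = {}
    for ci, comm in enumerate(communities):
        for node in comm:
            node_comm[node] = ci
    within = np.zeros(len(communities))
    strength = np.zeros(len(communities))
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d)
        cu, cv = node_comm[u], node_comm[v]
        strength[cu] += w
        strength[cv] += w
        if cu == cv:
            within[cu] += w
    return float(np.sum(within / m - (strength / (2 * m)) ** 2))


def detect_modules(g: nx.Graph) -> ModulePartition:
    """Fast-greedy (CNM) modularity maximisation with deterministic ties.

    Only connected community pairs are candidate merges (a merge across a
    zero-weight pair can never increase Q), so no module ever spans two
    components. Ties in the modularity gain are broken by the
    lexicographically smallest (representative, representative) pair,
    making the result deterministic.
    """
    if g.number_of_nodes() == 0:
        return ModulePartition({}, {}, 0.0)
    m = sum(_edge_weight(d) for _, _, d in g.edges(data=True))
    nodes = sorted(g.nodes, key=str)
    if m == 0:
        members = {f"module_{i + 1}": [n] for i, n in enumerate(nodes)}
        assignments = {n: mid for mid, mem in members.items() for n in mem}
        return ModulePartition(assignments, members, 0.0)

    # community state keyed by representative (min node label)
    comm_nodes = {n: {n} for n in nodes}
    strength = {n: sum(_edge_weight(d) for _, _, d in g.edges(n, data=True))
                for n in nodes}
    within = {n: 0.0 for n in nodes}
    between: dict = {}  # frozenset({a, b}) -> weight
    neighbors: dict = {n: set() for n in nodes}
    for u, v, d in g.edges(data=True):
        if u == v:
            continue
        key = frozenset((u, v))
        between[key] = between.get(key, 0.0) + _edge_weight(d)
        neighbors[u].add(v)
        neighbors[v].add(u)

    def current_q() -> float:
        return sum(within[c] / m - (strength[c] / (2 * m)) ** 2 for c in comm_nodes)

    best_q = current_q()
    best_partition = [set(s) for s in comm_nodes.values()]

    while len(comm_nodes) > 1 and between:
        best_gain, best_pair, best_key = -np.inf, None, None
        for key, w in between.items():
            a, b = sorted(key, key=str)
            gain = w / m - strength[a] * strength[b] / (2 * m * m)
            if gain > best_gain + 1e-15 or (
                abs(gain - best_gain) <= 1e-15
                and best_key is not None
                and (str(a), str(b)) < best_key
            ):
                best_gain, best_pair, best_key = gain, (a, b), (str(a), str(b))
        if best_pair is None:
            break
        a, b = best_pair
        # merge b into a (a is the smaller representative, keeps the key)
        comm_nodes[a] |= comm_nodes.pop(b)
        within[a] += within.pop(b) + between.pop(frozenset((a, b)))
        strength[a] += strength.pop(b)
        for c in list(neighbors[b]):
            if c == a:
                continue
            w = between.pop(frozenset((b, c)))
            key = frozenset((a, c))
            between[key] = between.get(key, 0.0) + w
            neighbors[c].discard(b)
            neighbors[c].add(a)
            neighbors[a].add(c)
        neighbors[a].discard(b)
        neighbors.pop(b)
        q = current_q()
        if q > best_q + 1e-12:
            best_q = q
            best_partition = [set(s) for s in comm_nodes.values()]

    return _label_partition(best_partition, best_q)


def _label_partition(communities, q: float, flagged=None) -> ModulePartition:
    """Stable module ids: module_1.. ordered by decreasing size then name."""
    ordered = sorted(communities, key=lambda s: (-len(s), min(map(str, s))))
    members, assignments = {}, {}
    flag_sets = [frozenset(s) for s in (flagged or [])]
    unassigned = set()
    for i, comm in enumerate(ordered):
        mid = f"module_{i + 1}"
        members[mid] = sorted(comm, key=str)
        for n in comm:
            assignments[n] = mid
        if frozenset(comm) in flag_sets:
            unassigned.add(mid)
    return ModulePartition(assignments, members, q, unassigned)


def enforce_min_size(p: ModulePartition, g: nx.Graph, min_size: int = 20) -> ModulePartition:
    """Merge modules smaller than *min_size* into their strongest neighbour.

    Iteratively, the smallest undersized module is merged into the
    neighbouring module sharing the greatest total |r| edge weight (ties:
    larger module, then lexicographically smallest member). Undersized
    modules with no network neighbours (isolated components) remain and
    are flagged as unassigned. Q is recomputed for the final partition.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    comms = [set(mem) for mem in p.members.values()]
    flagged: list = []

    def undersized():
        cands = [c for c in comms
                 if len(c) < min_size and frozenset(c) not in {frozenset(f) for f in flagged}]
        return sorted(cands, key=lambda c: (len(c), min(map(str, c))))

    while True:
        cands = undersized()
        if not cands:
            break
        small = cands[0]
        link = {}
        for i, other in enumerate(comms):
            if other is small:
                continue
            w = sum(_edge_weight(d) for u, v, d in g.edges(data=True)
                    if (u in small) != (v in small)
                    and (u in other or v in other))
            if w > 0:
                link[i] = w
        if not link:
            flagged.append(set(small))
            continue
        best = min(link.items(),
                   key=lambda kv: (-kv[1], -len(comms[kv[0]]),
                                   min(map(str, comms[kv[0]]))))
        target = comms[best[0]]
        target |= small
        comms.remove(small)

    q = weighted_modularity(g, comms)
    return _label_partition(comms, q, flagged=flagged)


def module_abundance(p: ModulePartition, t: FeatureTable) -> pd.DataFrame:
    """Samples x modules matrix of summed member relative abundances."""
    missing = [tx for tx in p.assignments if tx not in t.data.columns]
    if missing:
        raise KeyError(f"partition taxa absent from table: {sorted(missing)}")
    out = {}
    for mid, mem in p.members.items():
        out[mid] = t.data[mem].sum(axis=1) if mem else pd.Series(0.0, index=t.data.index)
    return pd.DataFrame(out, index=t.data.index)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ModuleNutrientAssociation:
    module: str
    nutrient: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stars: str
    degenerate: bool = False  # zero-variance module abundance


def module_nutrient_regression(abund: pd.Series, nutr: pd.Series,
                               module: str = "", nutrient: str = "") -> ModuleNutrientAssociation:
    """OLS of nutrient content on module relative abundance.

    Two-sided t-test p for the slope; stars at 0.05 / 0.01 / 0.001.
    """
    x = abund.to_numpy(dtype=float)
    y = nutr.loc[abund.index].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for regression")
    if np.var(x) == 0:
        return ModuleNutrientAssociation(module, nutrient, np.nan, np.nan,
                                         np.nan, np.nan, "", degenerate=True)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    if np.var(y) == 0:
        r2, p = 0.0, 1.0
    else:
        p = float(res.pvalue)
    return ModuleNutrientAssociation(module, nutrient, float(res.slope),
                                     float(res.intercept), r2, p, _stars(p))


def module_nutrient_table(abund: pd.DataFrame, nutrients: NutrientTable) -> pd.DataFrame:
    """All module x nutrient regressions, tidy, with a BH-adjusted column."""
    from .cooccurrence import adjust_fdr

    rows = []
    for mid in abund.columns:
        for var in nutrients.variables:
            a = module_nutrient_regression(abund[mid], nutrients.data[var], mid, var)
            rows.append(vars(a))
    df = pd.DataFrame(rows)
    valid = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = adjust_fdr(df.loc[valid, "p_value"].to_numpy())
    df["p_adj_bh"] = adj
    return df
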