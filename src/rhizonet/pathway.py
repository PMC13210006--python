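"""Tripartite microbe - enzyme gene - nutrient pathway screening.

Two bipartite Spearman screens (microbe vs gene, gene vs nutrient) at a
deliberately loose threshold (|r| > 0.60, raw p < 0.05 by default — looser
than the co-occurrence screen, and uncorrected, to keep biologically
meaningful weak links), then a relational join: a complete pathway
(microbe, gene, nutrient) requires both the microbe-gene and the
gene-nutrient edge to be retained simultaneously. The sign product of the
two edges labels the pathway "promotes" (+*+ or -*-) or "inhibits"
(mixed signs).

Enzyme-gene panels (KO/EC identifiers grouped by C/N/P cycle and
community) are editable JSON configuration; the shipped defaults are a
synthetic placeholder panel matching the typical panel sizes for a soil
C/N/P study (19/13/9 bacterial and 12/6/8 fungal genes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnzymeGenePanel",
    "TripartiteEdge",
    "CompletePathway",
    "load_gene_panels",
    "default_gene_panels",
    "screen_bipartite_edges",
    "enumerate_complete_pathways",
    "export_network",
]

CYCLES = ("C", "N", "P")


@dataclass
class EnzymeGenePanel:
    """A named list of enzyme genes for one nutrient cycle and community."""

    name: str
    cycle: str  # C / N / P
    community: str  # bacteria / fungi
    genes: dict  # gene id -> display name

    def __post_init__(self) -> None:
        if self.cycle not in CYCLES:
            raise ValueError(f"invalid cycle label {self.cycle!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in panel")


def load_gene_panels(path=None) -> list:
    """Load panels from JSON (defaults to the shipped placeholder config)."""
    if path is None:
        text = (
            resources.files("rhizonet.data")
            .joinpath("gene_panels_synthetic.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return [EnzymeGenePanel(**entry) for entry in raw]


def default_gene_panels() -> list:
    return load_gene_panels()


def gene_cycle_map(panels) -> dict:
    """gene id -> cycle label, across panels."""
    out = {}
    for panel in panels:
        for gid in panel.genes:
            out[gid] = panel.cycle
    return out


@dataclass
class TripartiteEdge:
    source: str
    target: str
    kind: str  # "microbe-gene" or "gene-nutrient"
    r: float
    p_raw: float
    retained: bool


def screen_bipartite_edges(a: pd.DataFrame, b: pd.DataFrame,
                           r_min: float = 0.60, p_max: float = 0.05,
                           kind: str = "microbe-gene") -> list:
    """Spearman screen of every (column of a) x (column of b) pair.

    Raw p from the t approximation; retained iff |r| > r_min and
    p_raw < p_max (no multiplicity correction at this loose screen).
    Zero-variance columns are excluded with a warning.
    """
    common = a.index.intersection(b.index)
    if len(common) < 4:
        raise ValueError("need at least 4 aligned samples")
    a = a.loc[common]
    b = b.loc[common]
    for df, side in ((a, "left"), (b, "right")):
        const = list(df.columns[df.var(axis=0) == 0])
        if const:
            warnings.warn(f"excluding zero-variance {side} columns: {const}")
            df.drop(columns=const, inplace=True)
    if a.shape[1] == 0 or b.shape[1] == 0:
        return []
    rho, pval = stats.spearmanr(a.to_numpy(), b.to_numpy())
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    na = a.shape[1]
    cross_r = rho[:na, na:]
    cross_p = pval[:na, na:]
    edges = []
    for i, u in enumerate(a.columns):
        for j, v in enumerate(b.columns):
            r, p = float(cross_r[i, j]), float(cross_p[i, j])
            edges.append(TripartiteEdge(u, v, kind, r, p,
                                        retained=abs(r) > r_min and p < p_max))
    return edges


@dataclass
class CompletePathway:
    microbe: str
    gene: str
    nutrient: str
    r_mg: float
    p_mg: float
    r_gn: float
    p_gn: float
    direction: str  # promotes / inhibits

    @property
    def triple(self) -> tuple:
        return (self.microbe, self.gene, self.nutrient)


def enumerate_complete_pathways(mg_edges, gn_edges) -> list:
    """Relational join of retained microbe-gene and gene-nutrient edges.

    One pathway per (m, g, n) with both edges retained; the direction label
    is the sign product convention: two like signs promote, mixed inhibit.
    """
    by_gene: dict = {}
    for e in gn_edges:
        if e.retained:
            by_gene.setdefault(e.source, []).append(e)
    out = []
    for mg in mg_edges:
        if not mg.retained:
            continue
        for gn in by_gene.get(mg.target, ()):
            direction = "promotes" if mg.r * gn.r > 0 else "inhibits"
            out.append(CompletePathway(mg.source, mg.target, gn.target,
                                       mg.r, mg.p_raw, gn.r, gn.p_raw, direction))
    return out


def pathways_frame(paths) -> pd.DataFrame:
    cols = ["microbe", "gene", "nutrient", "r_mg", "p_mg", "r_gn", "p_gn", "direction"]
    return pd.DataFrame([vars(p) for p in paths], columns=cols)


def export_network(paths, basepath, cycle_of: dict | None = None) -> None:
    """Write SIF + node-attribute TSV (+ GraphML) for Cytoscape.

    Node classes: microbe, C-gene / N-gene / P-gene (from *cycle_of*),
    nutrient. ``basepath`` gets suffixes ``.sif``, ``.nodes.tsv``,
    ``.graphml``.
    """
    cycle_of = cycle_of or {}
    basepath = str(basepath)
    g = nx.Graph()
    classes: dict = {}
    for p in paths:
        gene_class = f"{cycle_of.get(p.gene, 'C')}-gene"
        classes[p.microbe] = "microbe"
        classes[p.gene] = gene_class
        classes[p.nutrient] = "nutrient"
        g.add_edge(p.microbe, p.gene, r=p.r_mg, p_raw=p.p_mg, kind="microbe-gene")
        g.add_edge(p.gene, p.nutrient, r=p.r_gn, p_raw=p.p_gn, kind="gene-nutrient")
    with open(basepath + ".sif", "w") as fh:
        for u, v, d in g.edges(data=True):
            fh.write(f"{u}\t{d['kind']}\t{v}\n")
    with open(basepath + ".nodes.tsv", "w") as fh:
        fh.write("node\tclass\n")
        for node in sorted(classes):
            fh.write(f"{node}\t{classes[node]}\n")
    for node, cls in classes.items():
        g.nodes[node]["node_class"] = cls
    nx.write_graphml(g, basepath + ".graphml")
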