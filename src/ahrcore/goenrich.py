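"""Ontology-term enrichment with a permutation false-discovery rate.

Terms live on a rooted directed acyclic graph; gene annotations propagate
from descendants to ancestors, so every ancestor's annotated set contains
each descendant's.  Enrichment of a significant-gene set in a term is the
upper-tail hypergeometric probability of the term's changed-gene count,
restricted to terms annotating at least five universe genes.  The FDR of a
term is estimated by permutation: random gene sets of the same size are
drawn from the universe, and the FDR at a term's p-value is the mean null
count of terms at or below that p divided by the observed count, capped at
one.  Significant terms are traced root-ward to express higher-order
functional groupings, and per-study enriched-term sets are compared with
the same hypergeometric overlap machinery used for genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GoDag",
    "enrich_terms",
    "trace_to_roots",
    "term_overlap_between_studies",
]


class DagError(ValueError):
    pass


@dataclass
class GoDag:
    """A rooted term DAG with ancestor-propagated gene annotations.

    ``edges`` are (child, parent) pairs; ``annotations`` maps a term to the
    genes annotated *directly* to it.  On construction the graph is checked
    for cycles and every term's effective set becomes the union of its own
    and all descendants' direct annotations.
    """

    edges: list[tuple[str, str]]
    annotations: dict[str, set[str]]
    graph: nx.DiGraph = field(init=False, repr=False)
    propagated: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)  # edge: child -> parent
        for term in self.annotations:
            g.add_node(term)
        if not nx.is_directed_acyclic_graph(g):
            raise DagError("cycle detected in ontology edges")
        self.graph = g
        propagated: dict[str, set[str]] = {
            t: set(self.annotations.get(t, set())) for t in g.nodes
        }
        # children before parents: propagate along child -> parent edges
        for term in nx.topological_sort(g):
            for parent in g.successors(term):
                propagated[parent] |= propagated[term]
        self.propagated = propagated

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            raise DagError(f"unknown term {term!r}")
        return set(nx.descendants(self.graph, term))  # along child->parent

    def genes(self, term: str) -> set[str]:
        if term not in self.propagated:
            raise DagError(f"unknown term {term!r}")
        return self.propagated[term]

    def write_tsv(self, edges_path: str | Path, ann_path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["child", "parent"]).to_csv(
            edges_path, sep="\t", index=False
        )
        rows = [
            {"term": term, "gene": gene}
            for term in sorted(self.annotations)
            for gene in sorted(self.annotations[term])
        ]
        pd.DataFrame(rows, columns=["term", "gene"]).to_csv(
            ann_path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, edges_path: str | Path, ann_path: str | Path) -> "GoDag":
        edges = [
            (str(r.child), str(r.parent))
            for r in pd.read_csv(edges_path, sep="\t").itertuples()
        ]
        ann: dict[str, set[str]] = {}
        for r in pd.read_csv(ann_path, sep="\t").itertuples():
            ann.setdefault(str(r.term), set()).add(str(r.gene))
        return cls(edges=edges, annotations=ann)


def trace_to_roots(
    term: str, dag: GoDag, return_paths: bool = False
):
    """Root terms reachable from ``term`` by parent links.

    A root term traces to itself.  With ``return_paths`` the full list of
    root-ward paths (term ... root) is returned alongside the root set.
    """
    if term not in dag.graph:
        raise DagError(f"unknown term {term!r}")
    reachable = {term} | dag.ancestors(term)
    roots = reachable & dag.roots
    if not return_paths:
        return roots
    paths: list[list[str]] = []
    for root in sorted(roots):
        if root == term:
            paths.append([term])
            continue
        for path in nx.all_simple_paths(dag.graph, term, root):
            paths.append(list(path))
    return roots, paths


def enrich_terms(
    sig: Iterable[str],
    universe: Iterable[str],
    dag: GoDag,
    n_perm: int = 1000,
    min_size: int = 5,
    seed: int | np.random.Generator | None = None,
    fdr_threshold: float | None = None,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with permutation FDR.

    Terms annotating fewer than ``min_size`` universe genes are excluded.
    Returns one row per tested term: annotated/changed counts, expected
    count, enrichment (observed/expected), p, permutation FDR, the changed
    genes, and the root terms the term traces to.  With ``fdr_threshold``
    the table is filtered to terms at or below it.
    """
    sig = set(sig)
    universe_list = sorted(set(universe))
    universe = set(universe_list)
    if not sig:
        raise ValueError("empty significant set")
    if not sig <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    terms = [
        t for t in dag.terms if len(dag.genes(t) & universe) >= min_size
    ]
    if not terms:
        return pd.DataFrame(
            columns=["term", "n_annotated", "n_changed", "expected",
                     "enrichment", "p", "fdr", "changed_genes", "roots"]
        )
    n = len(universe)
    m = len(sig)
    gene_index = {g: i for i, g in enumerate(universe_list)}
    membership = np.zeros((len(terms), n), dtype=np.int64)
    k_ann = np.empty(len(terms), dtype=int)
    for t_i, term in enumerate(terms):
        idx = [gene_index[g] for g in dag.genes(term) & universe]
        membership[t_i, idx] = 1
        k_ann[t_i] = len(idx)

    sig_vec = np.zeros(n, dtype=np.int64)
    sig_vec[[gene_index[g] for g in sig]] = 1
    k_obs = membership @ sig_vec
    p_obs = stats.hypergeom.sf(k_obs - 1, n, k_ann, m)

    # permutation null: same-size random gene sets
    null_p = np.empty((n_perm, len(terms)))
    for r in range(n_perm):
        perm = np.zeros(n, dtype=np.int64)
        perm[rng.choice(n, size=m, replace=False)] = 1
        k_null = membership @ perm
        null_p[r] = stats.hypergeom.sf(k_null - 1, n, k_ann, m)

    fdr = np.empty(len(terms))
    for t_i in range(len(terms)):
        cut = p_obs[t_i]
        observed_at = int((p_obs <= cut).sum())
        null_at = float((null_p <= cut).sum(axis=1).mean())
        fdr[t_i] = min(1.0, null_at / observed_at) if observed_at else 1.0

    expected = k_ann * m / n
    rows = pd.DataFrame(
        {
            "term": terms,
            "n_annotated": k_ann,
            "n_changed": k_obs,
            "expected": expected,
            "enrichment": np.where(k_obs > 0, k_obs / expected, 0.0),
            "p": p_obs,
            "fdr": fdr,
            "changed_genes": [
                ",".join(sorted(dag.genes(t) & sig)) for t in terms
            ],
            "roots": [",".join(sorted(trace_to_roots(t, dag))) for t in terms],
        }
    ).sort_values(["p", "term"], kind="mergesort", ignore_index=True)
    if fdr_threshold is not None:
        rows = rows[rows["fdr"] < fdr_threshold].reset_index(drop=True)
    return rows


def term_overlap_between_studies(
    term_sets: Mapping[str, set[str]],
    n_terms: int,
) -> pd.DataFrame:
    """Pairwise hypergeometric overlap of enriched-term sets across studies.

    ``n_terms`` is the size of the tested-term universe.  Same machinery as
    the gene-level overlap, applied to terms.
    """
    from .overlap import all_pairwise

    return all_pairwise(dict(term_sets), n_terms)
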