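"""GO over-representation analysis of stage gene sets.

Annotations are propagated along ``is_a`` edges (true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor), then
each biological-process term is tested for over-representation in a
gene set with a one-sided hypergeometric (Fisher) test. Following the
study design this pipeline reproduces, no multiple-testing correction
is applied and terms are called significant at p < 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .core import ENRICHMENT_ALPHA, FragtxError

BIOLOGICAL_PROCESS = "biological_process"


@dataclass(eq=False)
class GoDag:
    """A gene-ontology DAG restricted to ``is_a`` edges.

    ``terms`` maps a term id to ``(name, namespace)``; ``parents`` maps a
    term id to its direct ``is_a`` parents. The edge set must be acyclic.
    """

    terms: dict[str, tuple[str, str]]
    parents: dict[str, set[str]]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge references undefined term {child}")
            for parent in ps:
                if parent not in self.terms:
                    raise ValueError(f"edge references undefined term {parent}")
                graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"is_a graph contains a cycle: {cycle}")
        self._graph = graph

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All ``is_a`` ancestors of ``term_id`` (excluding itself)."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        return self._ancestors_cached(term_id)

    @lru_cache(maxsize=None)  # noqa: B019 - cache lives with the DAG instance
    def _ancestors_cached(self, term_id: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._graph, term_id))

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def bp_terms(self) -> frozenset[str]:
        return frozenset(
            t for t, (_, ns) in self.terms.items() if ns == BIOLOGICAL_PROCESS
        )


def propagate_annotations(
    direct: dict[str, frozenset[str] | set[str]], dag: GoDag
) -> dict[str, frozenset[str]]:
    """Apply the true-path rule to direct gene -> GO annotations.

    Each gene becomes annotated to every ancestor of each of its direct
    terms. Idempotent; annotation sets only grow.

    Raises
    ------
    FragtxError
        if a direct annotation references a term absent from the DAG.
    """
    propagated: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        full: set[str] = set()
        for term in terms:
            if term not in dag.terms:
                raise FragtxError(f"gene {gene}: unknown GO term {term}")
            full.add(term)
            full.update(dag.ancestors(term))
        propagated[gene] = frozenset(full)
    return propagated


def term_test(
    set_size: int, universe_size: int, term_in_set: int, term_in_universe: int
) -> float:
    """One-sided over-representation p-value, P(X >= term_in_set).

    X follows the hypergeometric distribution of drawing ``set_size``
    genes from a universe of ``universe_size`` of which
    ``term_in_universe`` carry the term.
    """
    if not (
        0 <= term_in_set <= set_size <= universe_size
        and term_in_set <= term_in_universe <= universe_size
    ):
        raise FragtxError(
            "inconsistent counts: set_size="
            f"{set_size}, universe_size={universe_size}, term_in_set={term_in_set}, "
            f"term_in_universe={term_in_universe}"
        )
    return float(hypergeom.sf(term_in_set - 1, universe_size, term_in_universe, set_size))


def enrich(
    gene_set: set[str] | frozenset[str],
    annotations: dict[str, frozenset[str]],
    dag: GoDag,
    universe: set[str] | None = None,
    alpha: float = ENRICHMENT_ALPHA,
) -> pd.DataFrame:
    """Over-representation of biological-process terms in ``gene_set``.

    Parameters
    ----------
    gene_set
        Gene ids to test; must be a subset of the universe.
    annotations
        Propagated gene -> GO annotations (see :func:`propagate_annotations`).
    universe
        Background gene set. Defaults to all genes with at least one
        propagated biological-process annotation.
    alpha
        Significance threshold; no multiple-testing correction is applied.

    Returns
    -------
    One row per BP term annotated in the set, sorted by ascending
    p-value, with columns term, name, universe_count, set_count,
    expected, p_value, significant.
    """
    bp = dag.bp_terms()
    if universe is None:
        universe = {g for g, ts in annotations.items() if ts & bp}
    if not universe:
        raise FragtxError("empty annotation universe")
    extra = set(gene_set) - set(universe)
    if extra:
        raise FragtxError(f"gene set not contained in universe: {sorted(extra)[:5]}")

    universe_counts: dict[str, int] = {}
    set_counts: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, frozenset()) & bp:
            universe_counts[term] = universe_counts.get(term, 0) + 1
            if gene in gene_set:
                set_counts[term] = set_counts.get(term, 0) + 1

    n_set, n_universe = len(gene_set), len(universe)
    rows = []
    for term, k in set_counts.items():
        m = universe_counts[term]
        p = term_test(n_set, n_universe, k, m)
        rows.append(
            {
                "term": term,
                "name": dag.terms[term][0],
                "universe_count": m,
                "set_count": k,
                "expected": n_set * m / n_universe,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term",
            "name",
            "universe_count",
            "set_count",
            "expected",
            "p_value",
            "significant",
        ],
    )
    return result.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
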