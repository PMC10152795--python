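"""Gene-pair GO semantic similarity: term-level SimGIC aggregated with BMA.

Each GO sub-ontology (biological_process, molecular_function,
cellular_component) is treated independently.  Term information content
(IC) is estimated from the supplied annotation corpus with descendant
propagation: IC(t) = -log p(t) where p(t) is the fraction of annotated
genes whose propagated annotation set contains t, so the namespace root
has IC 0 and IC never decreases from root to leaf.  Term-term similarity
is SimGIC over reflexive ancestor sets (IC sum of shared ancestors over
IC sum of the ancestor union) and gene-gene similarity is the Best-Match
Average of the term-level values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet
import pandas as pd

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class Ontology:
    """is_a DAG with one root per namespace.

    ``parents`` maps a term to its direct is_a parents; every term must
    reach its namespace root through them.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]], namespace: Mapping[str, str]):
        self.parents = {t: tuple(ps) for t, ps in parents.items()}
        self.namespace = dict(namespace)
        for t in self.namespace:
            self.parents.setdefault(t, ())
        self._check_acyclic()
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a relation contains a cycle")

    def terms(self, namespace: Optional[str] = None) -> list[str]:
        if namespace is None:
            return list(self.namespace)
        return [t for t, ns in self.namespace.items() if ns == namespace]

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive is_a closure (term itself plus the root)."""
        if term not in self.namespace:
            raise KeyError(f"unknown term {term!r}")
        return self._ancestors(term)

    def _ancestors_uncached(self, term: str) -> frozenset[str]:
        out = {term}
        for p in self.parents.get(term, ()):
            out |= self._ancestors(p)
        return frozenset(out)


def ancestors(ontology: Ontology, term: str) -> frozenset[str]:
    return ontology.ancestors(term)


def read_obo(path) -> Ontology:
    """Read an OBO file (is_a edges and namespaces only)."""
    g = obonet.read_obo(path)
    parents: dict[str, list[str]] = {}
    namespace: dict[str, str] = {}
    for term, data in g.nodes(data=True):
        namespace[term] = data.get("namespace", "biological_process")
        parents[term] = [v for _, v, key in g.out_edges(term, keys=True) if key == "is_a"]
    return Ontology(parents, namespace)


def read_annotations(path) -> dict[str, set[str]]:
    """GAF-like TSV (gene_id, term_id) -> gene -> direct term set."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "term_id"} - set(table.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for gene, term in table[["gene_id", "term_id"]].itertuples(index=False, name=None):
        out.setdefault(gene, set()).add(term)
    return out


@dataclass
class AnnotationCorpus:
    """Gene annotations plus derived per-namespace information content."""

    ontology: Ontology
    gene_terms: Mapping[str, set[str]]

    def __post_init__(self):
        self.gene_terms = {g: set(ts) for g, ts in self.gene_terms.items()}
        self._ic: dict[str, float] = {}
        for ns in NAMESPACES:
            self._compute_ic(ns)

    def _compute_ic(self, ns: str) -> None:
        # propagated annotation: a gene annotated to t is annotated to
        # every ancestor of t
        counts: dict[str, int] = {}
        n_genes = 0
        for terms in self.gene_terms.values():
            closure: set[str] = set()
            for t in terms:
                if self.ontology.namespace.get(t) == ns:
                    closure |= self.ontology.ancestors(t)
            if closure:
                n_genes += 1
                for t in closure:
                    counts[t] = counts.get(t, 0) + 1
        # a term no gene maps to gets the namespace's maximal observed IC
        # (that of a singleton annotation), keeping IC monotone root->leaf
        max_ic = math.log(n_genes) if n_genes else 0.0
        for t in self.ontology.terms(ns):
            c = counts.get(t, 0)
            if n_genes == 0 or c == 0:
                self._ic[t] = max_ic
            else:
                self._ic[t] = -math.log(c / n_genes)

    def ic(self, term: str) -> float:
        if term not in self.ontology.namespace:
            raise KeyError(f"unknown term {term!r}")
        return self._ic[term]

    def namespace_terms(self, gene: str, ns: str) -> set[str]:
        return {
            t for t in self.gene_terms.get(gene, set())
            if self.ontology.namespace.get(t) == ns
        }


def simgic_terms(corpus: AnnotationCorpus, t1: str, t2: str) -> float:
    """SimGIC between two terms of one namespace: shared-ancestor IC sum
    over union-ancestor IC sum (0 when the union carries no IC)."""
    ont = corpus.ontology
    if ont.namespace[t1] != ont.namespace[t2]:
        raise ValueError(f"terms {t1!r} and {t2!r} are in different namespaces")
    a1, a2 = ont.ancestors(t1), ont.ancestors(t2)
    denom = sum(corpus.ic(t) for t in a1 | a2)
    if denom == 0.0:
        return 0.0
    return sum(corpus.ic(t) for t in a1 & a2) / denom


def gene_similarity_bma(
    corpus: AnnotationCorpus, terms1: Iterable[str], terms2: Iterable[str]
) -> Optional[float]:
    """Best-Match Average over the term-level SimGIC matrix.

    Returns ``None`` (missing, to be imputed upstream) when either term
    set is empty.
    """
    ts1, ts2 = list(terms1), list(terms2)
    if not ts1 or not ts2:
        return None
    sim = {(a, b): simgic_terms(corpus, a, b) for a in ts1 for b in ts2}
    best1 = sum(max(sim[(a, b)] for b in ts2) for a in ts1) / len(ts1)
    best2 = sum(max(sim[(a, b)] for a in ts1) for b in ts2) / len(ts2)
    return 0.5 * (best1 + best2)


def gene_pair_similarities(
    corpus: AnnotationCorpus, gene1: str, gene2: str
) -> dict[str, Optional[float]]:
    """BP/MF/CC similarities for one gene pair (None where unannotated)."""
    out: dict[str, Optional[float]] = {}
    for ns, key in zip(NAMESPACES, ("bp_sim", "mf_sim", "cc_sim")):
        out[key] = gene_similarity_bma(
            corpus,
            corpus.namespace_terms(gene1, ns),
            corpus.namespace_terms(gene2, ns),
        )
    return out
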