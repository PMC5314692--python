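"""Lightweight ontology annotation corpus with semantic similarity.

Holds a term DAG per namespace (biological process ``BP`` and molecular
function ``MF``), gene annotations propagated to all ancestors, term
information content IC(t) = -log(annotation frequency), Lin term
similarity and best-match-average (BMA) gene similarity. The
cross-namespace gene score averages BP and MF when both are defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Optional

from .core import InputError, ProteinId

log = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF")


@dataclass
class AnnotationCorpus:
    """Per-namespace DAG, ancestor closure and propagated gene annotations."""

    #: namespace -> term -> set of parents
    parents: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    #: namespace -> term -> ancestor closure (term itself included)
    ancestors: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    #: namespace -> gene -> propagated term set (drives IC and enrichment)
    annotations: dict[str, dict[ProteinId, frozenset[str]]] = field(default_factory=dict)
    #: namespace -> gene -> directly annotated terms (drives BMA similarity)
    direct: dict[str, dict[ProteinId, frozenset[str]]] = field(default_factory=dict)
    #: namespace -> term -> IC
    _ic: dict[str, dict[str, float]] = field(default_factory=dict)
    n_skipped_terms: int = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        gene_terms: Iterable[tuple[ProteinId, str]],
        dag_edges: Iterable[tuple[str, str, str]],
    ) -> "AnnotationCorpus":
        """Build from ``(gene, term)`` annotations and ``(child, parent,
        namespace)`` DAG edges.

        Annotations are propagated to all ancestors at build time. A cyclic
        DAG is an input error; a GAF term absent from the DAG is logged and
        skipped.
        """
        corpus = cls()
        for child, parent, ns in dag_edges:
            if ns not in NAMESPACES:
                raise InputError(f"unknown ontology namespace {ns!r}")
            d = corpus.parents.setdefault(ns, {})
            d.setdefault(child, set()).add(parent)
            d.setdefault(parent, set())
        for ns, par in corpus.parents.items():
            corpus.ancestors[ns] = _closure(par)
        term_ns = {t: ns for ns, par in corpus.parents.items() for t in par}
        raw: dict[str, dict[ProteinId, set[str]]] = {ns: {} for ns in corpus.parents}
        for gene, term in gene_terms:
            ns = term_ns.get(term)
            if ns is None:
                corpus.n_skipped_terms += 1
                continue
            raw[ns].setdefault(gene, set()).add(term)
        if corpus.n_skipped_terms:
            log.info("skipped %d annotations to terms absent from the DAG", corpus.n_skipped_terms)
        for ns, genes in raw.items():
            closure = corpus.ancestors[ns]
            corpus.direct[ns] = {g: frozenset(terms) for g, terms in genes.items()}
            corpus.annotations[ns] = {
                g: frozenset().union(*(closure[t] for t in terms)) for g, terms in genes.items()
            }
        corpus._compute_ic()
        return corpus

    def _compute_ic(self) -> None:
        for ns, genes in self.annotations.items():
            n = len(genes)
            counts: dict[str, int] = {}
            for terms in genes.values():
                for t in terms:
                    counts[t] = counts.get(t, 0) + 1
            self._ic[ns] = {
                t: -math.log(c / n) if n else 0.0 for t, c in counts.items()
            }

    # -- queries ----------------------------------------------------------

    def ic(self, term: str, namespace: str) -> float:
        """Information content; 0.0 for terms annotating every gene (root)."""
        return self._ic.get(namespace, {}).get(term, 0.0)

    def genes(self, namespace: Optional[str] = None) -> frozenset[ProteinId]:
        """Genes annotated in ``namespace`` (or in any namespace)."""
        if namespace is not None:
            return frozenset(self.annotations.get(namespace, {}))
        out: set[ProteinId] = set()
        for genes in self.annotations.values():
            out |= set(genes)
        return frozenset(out)

    def terms_of(
        self, gene: ProteinId, namespace: str, propagated: bool = True
    ) -> frozenset[str]:
        store = self.annotations if propagated else self.direct
        return store.get(namespace, {}).get(gene, frozenset())

    # -- similarity -------------------------------------------------------

    def lin(self, t1: str, t2: str, namespace: str) -> float:
        """Lin term similarity: 2·IC(MICA) / (IC(t1) + IC(t2)).

        The MICA is the shared ancestor (terms included) with maximal IC.
        Degenerates to 0 when both terms are uninformative (root-only).
        """
        anc = self.ancestors.get(namespace, {})
        common = anc.get(t1, frozenset()) & anc.get(t2, frozenset())
        denom = self.ic(t1, namespace) + self.ic(t2, namespace)
        if not common or denom <= 0.0:
            return 0.0
        mica = max(self.ic(t, namespace) for t in common)
        return min(1.0, 2.0 * mica / denom)

    def gene_similarity(self, g1: ProteinId, g2: ProteinId, namespace: str) -> Optional[float]:
        """Best-match-average gene similarity within one namespace.

        Runs over the genes' *direct* term sets (ancestors enter only
        through the MICA lookup), so a gene is perfectly similar to
        itself whenever its terms are informative. ``None`` when either
        gene is unannotated in the namespace.
        """
        ts1 = self.terms_of(g1, namespace, propagated=False)
        ts2 = self.terms_of(g2, namespace, propagated=False)
        if not ts1 or not ts2:
            return None
        sims = {(a, b): self.lin(a, b, namespace) for a in ts1 for b in ts2}
        row = sum(max(sims[(a, b)] for b in ts2) for a in ts1)
        col = sum(max(sims[(a, b)] for a in ts1) for b in ts2)
        return (row + col) / (len(ts1) + len(ts2))


def _closure(parents: dict[str, set[str]]) -> dict[str, frozenset[str]]:
    """Ancestor closure (reflexive) of a DAG; raises on cycles."""
    try:
        order = list(TopologicalSorter(parents).static_order())
    except CycleError as e:
        raise InputError(f"ontology DAG contains a cycle: {e.args[1]}") from e
    out: dict[str, frozenset[str]] = {}
    # static_order yields parents before children for parent-pointing maps
    for term in order:
        anc: set[str] = {term}
        for p in parents[term]:
            anc |= out[p]
        out[term] = frozenset(anc)
    return out


def gene_pair_gosim(
    g1: ProteinId, g2: ProteinId, corpus: AnnotationCorpus, namespace: Optional[str] = None
) -> Optional[float]:
    """Functional similarity of a gene pair in [0, 1].

    With ``namespace`` given, the BMA/Lin score in that namespace. Without,
    the cross-namespace score: the mean of the BP and MF scores when both
    are defined, else whichever is defined, else ``None`` (the undefined
    marker for pairs outside the annotated universe).
    """
    if namespace is not None:
        return corpus.gene_similarity(g1, g2, namespace)
    parts = [
        s for ns in NAMESPACES if (s := corpus.gene_similarity(g1, g2, ns)) is not None
    ]
    if not parts:
        return None
    return sum(parts) / len(parts)
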