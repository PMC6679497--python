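"""Functional synergy from Gene Ontology semantic similarity.

Term information content comes from cumulative annotation frequencies:
Freq(term) counts annotations to the term or any of its descendants, and
p(term) = Freq(term)/max(Freq) so the most frequent (most general) term
has p = 1. Two terms are compared with Lin's information-content ratio

    sim(t1, t2) = 2 log2 p(A*) / (log2 p(t1) + log2 p(t2))

where A* is their most informative common ancestor (MICA), the common
ancestor with the smallest p. The functional score of two target sets
averages gene-level similarities over all ordered cross pairs:

    S_function = 2 * sum_{i,j} sim(t_ki, t_hj) / ((m+n)(m+n-1))

which lies in [0, 1] because 2mn <= (m+n)(m+n-1) for m, n >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .errors import (DomainError, InputIOError, MissingAnnotationError,
                     OntologyError, UndefinedScoreError, warn)
from .tnetwork import TargetSet


@dataclass
class OntologyDAG:
    """Ontology terms and is_a parent links; obsolete terms flagged.

    ``parents`` maps each term to its direct is_a parents; the transpose
    (children) is derived on demand. The DAG is validated acyclic.
    """

    parents: dict[str, set[str]]
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("is_a relation contains a cycle")
        self._graph = g

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> set[str]:
        """Reflexive ancestor set: the term plus everything above it."""
        return {term} | nx.descendants(self._graph, term)

    def descendants(self, term: str) -> set[str]:
        """Reflexive descendant set."""
        return {term} | nx.ancestors(self._graph, term)


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 ontology (id / is_a / is_obsolete honoured).

    is_a edges pointing at undefined terms are dropped with a warning;
    obsolete terms are retained in the DAG but flagged so similarity
    queries can exclude them.
    """
    path = Path(path)
    try:
        g = obonet.read_obo(path, ignore_obsolete=False)
    except OSError as exc:
        raise InputIOError(f"cannot read ontology {path}: {exc}") from exc
    except ValueError as exc:
        raise OntologyError(f"malformed OBO file {path}: {exc}") from exc
    # nodes created only as edge targets have no stanza -> dangling is_a
    defined = {n for n, data in g.nodes(data=True) if data}
    parents: dict[str, set[str]] = {t: set() for t in defined}
    obsolete = {n for n, data in g.nodes(data=True)
                if str(data.get("is_obsolete", "")).lower() == "true"}
    n_dangling = 0
    for child, parent, key in g.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in defined:
            n_dangling += 1
            continue
        parents[child].add(parent)
    if n_dangling:
        warn(f"{path}: dropped {n_dangling} is_a edge(s) to undefined terms",
             code="ontology.dangling_is_a")
    return OntologyDAG(parents, obsolete)


class GOAnnotationCorpus:
    """Ontology DAG plus gene annotations and cumulative term frequencies.

    Parameters
    ----------
    dag
        The parsed ontology.
    gene_terms
        Mapping gene id -> set of annotated term ids. Annotations to
        unknown or obsolete terms are dropped with a warning.
    """

    def __init__(self, dag: OntologyDAG, gene_terms: dict[str, set[str]]):
        self.dag = dag
        valid = dag.terms - dag.obsolete
        dropped = 0
        self.gene_terms: dict[str, set[str]] = {}
        direct: dict[str, int] = {}
        for gene, terms in gene_terms.items():
            keep = set()
            for t in terms:
                if t in valid:
                    keep.add(t)
                    direct[t] = direct.get(t, 0) + 1
                else:
                    dropped += 1
            self.gene_terms[gene] = keep
        if dropped:
            warn(f"dropped {dropped} annotation(s) to unknown or obsolete "
                 "terms", code="ontology.bad_annotation")
        # cumulative frequency: annotations to the term or any descendant
        self.freq: dict[str, int] = {}
        for term in dag.terms:
            self.freq[term] = sum(direct.get(d, 0)
                                  for d in dag.descendants(term))
        self.max_freq = max(self.freq.values(), default=0)
        if self.max_freq == 0:
            raise MissingAnnotationError("annotation corpus is empty")

    @classmethod
    def from_files(cls, obo_path: str | Path,
                   annotations_path: str | Path) -> "GOAnnotationCorpus":
        """Build from an OBO file and a two-column (gene, term) TSV."""
        dag = parse_obo(obo_path)
        try:
            df = pd.read_csv(annotations_path, sep="\t", comment="#",
                             header=None, names=["gene", "term"], dtype=str)
        except OSError as exc:
            raise InputIOError(
                f"cannot read annotations {annotations_path}: {exc}") from exc
        gene_terms: dict[str, set[str]] = {}
        for gene, term in df.itertuples(index=False):
            gene_terms.setdefault(gene, set()).add(term)
        return cls(dag, gene_terms)

    def restricted_to(self, genes: set[str]) -> "GOAnnotationCorpus":
        """Corpus with frequencies recomputed from the given genes only."""
        sub = {g: t for g, t in self.gene_terms.items() if g in genes}
        return GOAnnotationCorpus(self.dag, sub)

    def term_probability(self, term: str) -> float:
        """p(term) = cumulative Freq(term) / max Freq, in (0, 1]."""
        f = self.freq.get(term, 0)
        if f == 0:
            raise MissingAnnotationError(
                f"term {term!r} has no (cumulative) annotations")
        return f / self.max_freq

    def term_similarity(self, t1: str, t2: str,
                        mica_rule: str = "mica") -> float:
        """Lin similarity of two annotated terms, in [0, 1].

        ``mica_rule='mica'`` scores through the common ancestor with
        minimum p (maximum information content); ``'literal_max'`` uses
        the ancestor with maximum p, which on a rooted DAG is always the
        root and drives the similarity to 0.
        """
        if mica_rule not in ("mica", "literal_max"):
            raise DomainError(f"mica_rule {mica_rule!r} not in "
                              "('mica', 'literal_max')")
        for t in (t1, t2):
            if t in self.dag.obsolete:
                raise MissingAnnotationError(f"term {t!r} is obsolete")
        p1 = self.term_probability(t1)
        p2 = self.term_probability(t2)
        if t1 == t2:
            return 1.0
        common = self.dag.ancestors(t1) & self.dag.ancestors(t2)
        common = {a for a in common if self.freq.get(a, 0) > 0}
        if not common:
            warn(f"terms {t1!r}, {t2!r} share no annotated ancestor",
                 code="ontology.no_common_ancestor")
            return 0.0
        pick = min if mica_rule == "mica" else max
        p_anc = pick(self.term_probability(a) for a in common)
        denom = math.log2(p1) + math.log2(p2)
        if denom == 0.0:  # both terms maximally frequent but distinct
            return 0.0
        return 2.0 * math.log2(p_anc) / denom

    def gene_pair_similarity(self, g1: str, g2: str,
                             aggregation: str = "max",
                             mica_rule: str = "mica") -> float:
        """Similarity of two genes' annotation sets, in [0, 1].

        Aggregates term-pair similarities over the annotation cross
        product: ``max`` (default), ``bma`` (best-match average) or
        ``avg``. An unannotated gene scores 0 against everything.
        """
        if aggregation not in ("max", "bma", "avg"):
            raise DomainError(f"aggregation {aggregation!r} not in "
                              "('max', 'bma', 'avg')")
        a1 = self.gene_terms.get(g1, set())
        a2 = self.gene_terms.get(g2, set())
        if not a1 or not a2:
            missing = g1 if not a1 else g2
            warn(f"gene {missing!r} is unannotated; similarity set to 0",
                 code="ontology.unannotated_gene")
            return 0.0
        sims = {(t1, t2): self.term_similarity(t1, t2, mica_rule)
                for t1 in a1 for t2 in a2}
        if aggregation == "max":
            return max(sims.values())
        if aggregation == "avg":
            return sum(sims.values()) / len(sims)
        best1 = [max(sims[(t1, t2)] for t2 in a2) for t1 in a1]
        best2 = [max(sims[(t1, t2)] for t1 in a1) for t2 in a2]
        return (sum(best1) + sum(best2)) / (len(best1) + len(best2))


def s_function(Tk: TargetSet, Th: TargetSet, corpus: GOAnnotationCorpus,
               aggregation: str = "max", mica_rule: str = "mica") -> float:
    """Functional synergy score of two target sets, in [0, 1].

    Sums gene-pair similarities over both orientations of every cross
    pair and divides by the ordered-pair count (m+n)(m+n-1).
    """
    m, n = Tk.size, Th.size
    if m == 0 or n == 0:
        raise UndefinedScoreError(
            f"functional score needs non-empty target sets "
            f"({Tk.drug_id!r}: {m}, {Th.drug_id!r}: {n})")
    total = 0.0
    for tki in Tk.targets:
        for thj in Th.targets:
            total += corpus.gene_pair_similarity(tki, thj, aggregation,
                                                 mica_rule)
    return 2.0 * total / ((m + n) * (m + n - 1))
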