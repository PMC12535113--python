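"""Deepest-GO-term assignment and shared-function z-tests.

Each transcript is assigned, per namespace, its deepest annotated GO term
(depth = longest path from the namespace root, the convention under which
"deepest" means most specific); a set-wide non-overlap pass then replaces
chosen terms that are ancestors of other chosen terms. Functional overlap
between the highly divergent and differentially expressed candidate-gene
transcript sets is summarized per namespace and compared against transcript
overlap with pooled two-proportion z-tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

NAMESPACES = ("BP", "MF", "CC")


@dataclass
class GODag:
    """GO DAG (child -> parent edges) with one root per namespace."""

    graph: nx.DiGraph  # edges child -> parent
    namespace: dict  # term -> namespace

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "GODag":
        graph = nx.DiGraph()
        namespace: dict = {}
        for row in edges.itertuples(index=False):
            graph.add_edge(row.child, row.parent)
            for term in (row.child, row.parent):
                prev = namespace.setdefault(term, row.namespace)
                if prev != row.namespace:
                    raise ValueError(f"term {term} assigned to two namespaces")
        dag = cls(graph=graph, namespace=namespace)
        dag.validate()
        return dag

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO graph contains a cycle")
        for ns in set(self.namespace.values()):
            terms = [t for t, n in self.namespace.items() if n == ns]
            roots = [t for t in terms if self.graph.out_degree(t) == 0]
            if len(roots) != 1:
                raise ValueError(f"namespace {ns} has {len(roots)} roots, expected 1")

    def root(self, ns: str) -> str:
        return next(
            t for t, n in self.namespace.items() if n == ns and self.graph.out_degree(t) == 0
        )

    def depth(self, term: str) -> int:
        """Longest path from the term up to its namespace root."""
        if not hasattr(self, "_depth_cache"):
            self._depth_cache: dict = {}
        cache = self._depth_cache
        if term in cache:
            return cache[term]
        # parents of t are the successors of t in the child->parent graph
        for t in nx.topological_sort(self.graph.reverse()):
            parents = list(self.graph.successors(t))
            cache[t] = 0 if not parents else 1 + max(cache[p] for p in parents)
        return cache[term]

    def n_descendants(self, term: str) -> int:
        """Number of (strict) descendant terms below this term."""
        return len(nx.ancestors(self.graph, term))

    def is_ancestor(self, a: str, b: str) -> bool:
        """True when ``a`` is a strict ancestor of ``b``."""
        return a != b and nx.has_path(self.graph, b, a)

    def terms(self, ns: str) -> list[str]:
        return [t for t, n in self.namespace.items() if n == ns]


def _pick_deepest(dag: GODag, candidates: list[str]) -> str:
    # deepest; ties by fewest descendants, then lexicographic term ID
    return min(candidates, key=lambda t: (-dag.depth(t), dag.n_descendants(t), t))


def deepest_assignment(annotations: pd.DataFrame, dag: GODag) -> pd.DataFrame:
    """One GO term per transcript per annotated namespace.

    Per transcript and namespace the deepest annotated term is chosen
    (ties: fewest descendants, then term ID). Non-overlap is enforced
    set-wide: a chosen term that is an ancestor of another chosen term in
    the same namespace is replaced by the transcript's deepest annotated
    alternative that is not an ancestor of any other chosen term, when one
    exists; the pass repeats (in sorted transcript order) until stable.
    Annotations to terms absent from the DAG are dropped with a warning.
    """
    known = set(dag.namespace)
    missing = set(annotations["go_id"]) - known
    if missing:
        warnings.warn(f"{len(missing)} annotated terms absent from the DAG; dropped")
        annotations = annotations[annotations["go_id"].isin(known)]
    rows = []
    by_transcript: dict = {}
    for row in annotations.itertuples(index=False):
        ns = dag.namespace[row.go_id]
        by_transcript.setdefault((row.transcript, ns), set()).add(row.go_id)
    chosen = {
        key: _pick_deepest(dag, sorted(terms)) for key, terms in by_transcript.items()
    }
    for _ in range(10):  # set-wide non-overlap fixed point
        changed = False
        for ns in sorted({ns for _, ns in chosen}):
            keys = sorted(k for k in chosen if k[1] == ns)
            for key in keys:
                term = chosen[key]
                others = {chosen[k] for k in keys if k != key}
                if not any(dag.is_ancestor(term, o) for o in others):
                    continue
                alternatives = [
                    t
                    for t in sorted(by_transcript[key])
                    if not any(dag.is_ancestor(t, o) for o in others)
                ]
                if alternatives:
                    replacement = _pick_deepest(dag, alternatives)
                    if replacement != term:
                        chosen[key] = replacement
                        changed = True
        if not changed:
            break
    for (transcript, ns), term in sorted(chosen.items()):
        rows.append(
            {"transcript": transcript, "namespace": ns, "term": term, "depth": dag.depth(term)}
        )
    return pd.DataFrame(rows, columns=["transcript", "namespace", "term", "depth"])


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test (no continuity correction), two-sided."""
    if n1 == 0 or n2 == 0:
        return float("nan"), float("nan")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def overlap_ztest(hd_set: set, de_set: set, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-namespace overlap of HD and DE transcript sets and their GO terms.

    For each namespace: shared transcripts = HD intersect DE (restricted to
    transcripts assigned in that namespace); shared terms = intersection of
    the two sets' assigned-term sets. Directional percentages divide by the
    HD (respectively DE) side, and a pooled two-proportion z-test compares
    the shared-term proportion against the shared-transcript proportion in
    each direction.
    """
    if not hd_set or not de_set:
        raise ValueError("both transcript sets must be non-empty")
    rows = []
    for ns in sorted(assignments["namespace"].unique()):
        sub = assignments[assignments["namespace"] == ns]
        assigned = dict(zip(sub["transcript"], sub["term"]))
        hd = {t for t in hd_set if t in assigned}
        de = {t for t in de_set if t in assigned}
        terms_hd = {assigned[t] for t in hd}
        terms_de = {assigned[t] for t in de}
        shared_tx = hd & de
        shared_terms = terms_hd & terms_de
        def pct(k, n):
            return 100.0 * k / n if n else np.nan
        z_hd, p_hd = two_proportion_ztest(
            len(shared_terms), len(terms_hd), len(shared_tx), len(hd)
        ) if hd and terms_hd else (np.nan, np.nan)
        z_de, p_de = two_proportion_ztest(
            len(shared_terms), len(terms_de), len(shared_tx), len(de)
        ) if de and terms_de else (np.nan, np.nan)
        rows.append(
            {
                "namespace": ns,
                "n_cgt_hd": len(hd),
                "n_cgt_de": len(de),
                "n_terms_hd": len(terms_hd),
                "n_terms_de": len(terms_de),
                "n_shared_transcripts": len(shared_tx),
                "n_shared_terms": len(shared_terms),
                "shared_transcript_pct_hd": pct(len(shared_tx), len(hd)),
                "shared_transcript_pct_de": pct(len(shared_tx), len(de)),
                "shared_term_pct_hd": pct(len(shared_terms), len(terms_hd)),
                "shared_term_pct_de": pct(len(shared_terms), len(terms_de)),
                "z_hd": z_hd,
                "p_hd": p_hd,
                "z_de": z_de,
                "p_de": p_de,
            }
        )
    return pd.DataFrame(rows)
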