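"""GO hierarchy levels, umbrella-term enrichment and keyword word-mining.

The ontology is consumed as two TSVs (terms: id/name/namespace; edges:
child is_a parent) and held as a :class:`networkx.DiGraph` with edges
pointing child -> parent. Only the biological_process namespace is used;
its root is hierarchy level 1 and a term's level is one plus the length
of its *shortest* is_a path to the root (GO terms reach the root along
paths of several lengths; the shortest-path convention is deterministic
and reproduces the canonical worked chain signaling=2, cytokine
production=3, type I interferon production=4).

Level-3 terms are aggregated into ~20 manually defined umbrella labels;
overrepresentation of each umbrella in a DEG cluster against the
background is the hypergeometric upper tail with BH adjustment across
the umbrellas of one cluster analysis.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .errors import AnnotationError, DataError

BIOLOGICAL_PROCESS = "biological_process"

#: default word-mining keywords; "necrosis" and "necroptosis" are both
#: included because the two phrasings select different term names.
DEFAULT_KEYWORDS = ("DNA damage", "DNA repair", "necrosis", "necroptosis", "apoptosis")


@dataclass
class GOGraph:
    """A GO DAG restricted to one namespace, with child->parent is_a edges."""

    graph: nx.DiGraph
    root: str
    names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tables(cls, terms: pd.DataFrame, edges: pd.DataFrame,
                    namespace: str = BIOLOGICAL_PROCESS) -> "GOGraph":
        """Build from a term table (id, name, namespace) and an edge table
        (child, parent). The namespace root is the unique term without
        parents; cycles are rejected."""
        terms = terms[terms["namespace"] == namespace]
        ids = set(terms["id"])
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for _, row in edges.iterrows():
            if row["child"] in ids and row["parent"] in ids:
                g.add_edge(row["child"], row["parent"])
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("GO edge table contains a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise DataError(f"expected one {namespace} root, found {len(roots)}")
        names = dict(zip(terms["id"], terms["name"]))
        return cls(graph=g, root=roots[0], names=names)

    @classmethod
    def read(cls, terms_path: str | Path, edges_path: str | Path,
             namespace: str = BIOLOGICAL_PROCESS) -> "GOGraph":
        terms = pd.read_csv(terms_path, sep="\t")
        edges = pd.read_csv(edges_path, sep="\t")
        return cls.from_tables(terms, edges, namespace)


def compute_levels(go: GOGraph) -> tuple[dict[str, int], list[str]]:
    """Term -> hierarchy level (root = 1, shortest is_a path + 1).

    Terms not connected to the root are excluded and returned in the
    second element for reporting.
    """
    level = {go.root: 1}
    queue = deque([go.root])
    # BFS over reversed edges (parent -> children)
    children: dict[str, list[str]] = {n: [] for n in go.graph.nodes}
    for child, parent in go.graph.edges:
        children[parent].append(child)
    while queue:
        node = queue.popleft()
        for c in sorted(children[node]):
            if c not in level:
                level[c] = level[node] + 1
                queue.append(c)
    disconnected = sorted(set(go.graph.nodes) - set(level))
    return level, disconnected


def annotate_genes(direct: dict[str, set[str]], go: GOGraph) -> dict[str, set[str]]:
    """Close each gene's direct annotations under is_a ancestry (true-path).

    Unknown term ids are skipped (collected once per call and reported
    via the returned annotation's ``"__unknown__"`` pseudo-entry being
    absent -- they simply do not contribute).
    """
    anc_cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in anc_cache:
            anc_cache[term] = set(nx.descendants(go.graph, term))  # edges point upward
        return anc_cache[term]

    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in go.graph:
                continue
            closed.add(t)
            closed |= ancestors(t)
        out[gene] = closed
    return out


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV gene_id \\t term_id (one pair per line)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        out.setdefault(g, set()).add(t)
    return out


def read_umbrella_map(path: str | Path) -> dict[str, str]:
    """TSV term_id \\t umbrella_label mapping level-3 terms to umbrellas."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "umbrella"],
                     dtype=str, comment="#")
    if df["term_id"].duplicated().any():
        dup = df.loc[df["term_id"].duplicated(), "term_id"].tolist()
        raise AnnotationError(f"terms mapped to more than one umbrella: {dup[:5]}")
    return dict(zip(df["term_id"], df["umbrella"]))


def umbrella_abundance(genes: set[str], annotation: dict[str, set[str]],
                       umbrella_map: dict[str, str]) -> dict[str, int]:
    """Umbrella -> number of genes carrying >=1 of its terms.

    A gene counts once per umbrella however many of that umbrella's
    terms it carries, but may count toward several umbrellas, so the
    abundances can sum to more than the number of genes.
    """
    counts: dict[str, int] = {u: 0 for u in sorted(set(umbrella_map.values()))}
    for gene in genes:
        hit = {umbrella_map[t] for t in annotation.get(gene, set()) if t in umbrella_map}
        for u in hit:
            counts[u] += 1
    return counts


def overrepresentation(cluster: set[str], background: set[str],
                       annotation: dict[str, set[str]],
                       umbrella_map: dict[str, str],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-umbrella hypergeometric overrepresentation of a cluster.

    Columns: umbrella, k (cluster genes with the umbrella), n (cluster
    size), K (background genes with it), N (background size),
    enrichment_factor = (k/n)/(K/N), p = P(X >= k), padj (BH across
    umbrellas), overrepresented (padj < alpha).
    """
    if not background:
        raise DataError("empty background set")
    if not cluster <= background:
        raise DataError("cluster is not a subset of the background")
    bg_counts = umbrella_abundance(background, annotation, umbrella_map)
    cl_counts = umbrella_abundance(cluster, annotation, umbrella_map)
    N, n = len(background), len(cluster)
    rows = []
    for u in sorted(bg_counts):
        K, k = bg_counts[u], cl_counts.get(u, 0)
        ef = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append({"umbrella": u, "k": k, "n": n, "K": K, "N": N,
                     "enrichment_factor": ef, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["padj"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    out["overrepresented"] = out["padj"] < alpha
    return out


def wordcloud_sizes(abundances: dict[str, int],
                    lo: float = 10.0, hi: float = 30.0) -> dict[str, float]:
    """Linear map of per-cluster abundances onto font sizes [lo, hi].

    The smallest abundance gets ``lo``, the largest ``hi``; when all
    abundances are equal every label gets the midpoint.
    """
    if not abundances:
        raise DataError("empty abundance map")
    vals = list(abundances.values())
    a_min, a_max = min(vals), max(vals)
    if a_max == a_min:
        mid = (lo + hi) / 2.0
        return {u: mid for u in abundances}
    scale = (hi - lo) / (a_max - a_min)
    return {u: lo + (v - a_min) * scale for u, v in abundances.items()}


def word_mine(annotation: dict[str, set[str]], go: GOGraph,
              keywords: tuple[str, ...] = DEFAULT_KEYWORDS) -> set[str]:
    """Genes with >=1 annotated term whose name contains any keyword.

    Matching is case-insensitive substring search against the term
    names, so e.g. "apoptosis" selects "intrinsic apoptotic signaling
    pathway" only if the keyword itself occurs -- keyword stems such as
    "apopto" can be supplied to widen the net.
    """
    if not keywords:
        raise DataError("keyword set is empty")
    keys = [k.lower() for k in keywords]
    matching_terms = {t for t, name in go.names.items()
                      if any(k in name.lower() for k in keys)}
    return {g for g, terms in annotation.items() if terms & matching_terms}
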