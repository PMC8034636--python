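"""Functional standards: reference pair sets against which co-complex pairs are judged.

Four standards are built here, each with an explicit tested universe so that
enrichment is always computed over pairs for which functional data exist:

* **Genetic interaction** -- per-screen outcomes (negative / positive / none)
  are consensus-called per gene pair: a sign is assigned when at least half of
  that pair's screens report it. Hypomorphic DAmP alleles are dropped before
  calling (they rarely perturb fitness enough to score).
* **Co-expression** -- pairs whose integrated co-expression score is strictly
  above a cutoff (1.0 for MEFIT-style scores).
* **Co-localization** -- pairs sharing at least one annotated compartment.
* **Co-annotation** -- pairs sharing at least one biological-process GO term
  after up-propagation through the is_a/part_of DAG, with very frequently
  annotated terms removed.

The module also builds bespoke GO SLIMs: descendant closure of hand-picked
high-level terms, used to classify complexes via their complex-level GO
annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import ComplexDataset
from .pairs import Pair, PairSet, pair

__all__ = [
    "GIStandard",
    "Ontology",
    "read_gi_screens",
    "consensus_genetic_interactions",
    "coexpression_standard",
    "colocalization_standard",
    "coannotation_standard",
    "read_obo",
    "read_ontology_edges",
    "read_annotations",
    "read_localizations",
    "read_coexpression_scores",
    "descendant_closure",
    "propagate_annotations",
    "classify_complexes_by_slim",
]

logger = logging.getLogger(__name__)

GI_OUTCOMES = ("negative", "positive", "none")
PERTURBATIONS = ("deletion", "temperature_sensitive", "damp")


@dataclass
class GIStandard:
    """Consensus genetic-interaction sign per tested gene pair."""

    sign: dict[Pair, str]
    tested: set[Pair] = field(default_factory=set)

    def pairs_with(self, outcome: str) -> PairSet:
        if outcome not in GI_OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}")
        return PairSet(
            f"gi:{outcome}", {p for p, s in self.sign.items() if s == outcome}
        )


@dataclass
class Ontology:
    """is_a/part_of DAG over terms; edges point child -> parent."""

    graph: nx.DiGraph
    namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """Term plus all transitive parents."""
        return {term} | nx.descendants(self.graph, term)


# --------------------------------------------------------------------------
# Genetic interactions
# --------------------------------------------------------------------------


def read_gi_screens(path) -> pd.DataFrame:
    """Read a 4-column GI screen TSV: orf_a, orf_b, perturbation, outcome."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["orf_a", "orf_b", "perturbation", "outcome"],
        dtype=str,
    )
    bad = set(df["outcome"]) - set(GI_OUTCOMES)
    if bad:
        raise ValueError(f"unknown GI outcomes {sorted(bad)}")
    bad = set(df["perturbation"]) - set(PERTURBATIONS)
    if bad:
        raise ValueError(f"unknown perturbation types {sorted(bad)}")
    return df


def consensus_genetic_interactions(
    screens: pd.DataFrame, drop_damp: bool = True
) -> GIStandard:
    """Consensus-call genetic interactions across repeated screens of a pair.

    A pair receives a sign when at least half of its (non-DAmP) screens report
    that sign, i.e. ``2 * count >= total``. Screens are counted per gene pair
    across all query alleles. If both negative and positive independently
    reach half (possible with exactly two discordant screens), the call is
    ``none`` and the conflict is logged. Pairs whose only screens were DAmP
    vanish from the tested universe when ``drop_damp`` is set.
    """
    if screens.empty:
        raise ValueError("empty screen table")
    df = screens
    if drop_damp:
        df = df[df["perturbation"] != "damp"]
    sign: dict[Pair, str] = {}
    tested: set[Pair] = set()
    counts: dict[Pair, dict[str, int]] = {}
    for a, b, outcome in zip(df["orf_a"], df["orf_b"], df["outcome"]):
        p = pair(a, b)
        counts.setdefault(p, {"negative": 0, "positive": 0, "none": 0})[outcome] += 1
    for p, c in counts.items():
        tested.add(p)
        total = sum(c.values())
        neg = 2 * c["negative"] >= total and c["negative"] > 0
        pos = 2 * c["positive"] >= total and c["positive"] > 0
        if neg and pos:
            logger.warning("conflicting consensus for pair %s: %s", p, c)
            sign[p] = "none"
        elif neg:
            sign[p] = "negative"
        elif pos:
            sign[p] = "positive"
        else:
            sign[p] = "none"
    return GIStandard(sign=sign, tested=tested)


# --------------------------------------------------------------------------
# Co-expression
# --------------------------------------------------------------------------


def read_coexpression_scores(path) -> dict[Pair, float]:
    """Read a 3-column TSV (protein_a, protein_b, score) of co-expression scores."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["a", "b", "score"], dtype={"a": str, "b": str, "score": float},
    )
    return {pair(a, b): s for a, b, s in zip(df["a"], df["b"], df["score"])}


def coexpression_standard(
    scores: dict[Pair, float], cutoff: float = 1.0
) -> tuple[PairSet, set[Pair]]:
    """Pairs with score strictly greater than ``cutoff``; universe = scored pairs."""
    std = {p for p, s in scores.items() if s > cutoff}
    return PairSet("coexpression", std), set(scores)


# --------------------------------------------------------------------------
# Co-localization
# --------------------------------------------------------------------------


def read_localizations(path) -> dict[str, frozenset[str]]:
    """Read a 2-column TSV (protein, compartment); multiple rows per protein."""
    locs: dict[str, set[str]] = {}
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["protein", "compartment"], dtype=str,
    )
    for p, c in zip(df["protein"], df["compartment"]):
        locs.setdefault(p, set()).add(c)
    return {k: frozenset(v) for k, v in locs.items()}


def colocalization_standard(
    locs: dict[str, frozenset[str]],
    candidate_pairs: set[Pair] | None = None,
) -> tuple[PairSet, set[Pair]]:
    """Pairs sharing >= 1 compartment; universe = pairs with both proteins annotated.

    With ``candidate_pairs`` given, only those are classified (the usual case:
    the co-complex and background pairs of a dataset); otherwise all pairs over
    annotated proteins are enumerated.
    """
    annotated = {p for p, cs in locs.items() if cs}
    if candidate_pairs is None:
        from itertools import combinations

        candidate_pairs = set(combinations(sorted(annotated), 2))
    universe = {p for p in candidate_pairs if p[0] in annotated and p[1] in annotated}
    std = {p for p in universe if locs[p[0]] & locs[p[1]]}
    return PairSet("colocalization", std), universe


# --------------------------------------------------------------------------
# Ontology and annotations
# --------------------------------------------------------------------------


def read_obo(path) -> Ontology:
    """Load an OBO flat file; only is_a and part_of edges are kept."""
    import obonet

    g = obonet.read_obo(path)
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        graph.add_node(node)
        namespace[node] = data.get("namespace", "")
    for child, parent, key in g.edges(keys=True):
        if key in ("is_a", "part_of"):
            graph.add_edge(child, parent)
    return Ontology(graph=graph, namespace=namespace)


def read_ontology_edges(path, namespaces: dict[str, str] | None = None) -> Ontology:
    """Load an ontology from a 2-column child<TAB>parent edge TSV.

    An optional third column carries the child term's namespace.
    """
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            child, parent = cols[0].strip(), cols[1].strip()
            if parent:
                graph.add_edge(child, parent)
            else:
                graph.add_node(child)
            if len(cols) > 2:
                namespace[child] = cols[2].strip()
    if namespaces:
        namespace.update(namespaces)
    return Ontology(graph=graph, namespace=namespace)


def read_annotations(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read GAF-like 3-column TSV (entity, term, namespace).

    Returns entity -> term set, and term -> namespace (from column 3).
    """
    ann: dict[str, set[str]] = {}
    ns: dict[str, str] = {}
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["entity", "term", "namespace"], dtype=str,
    )
    for e, t, n in zip(df["entity"], df["term"], df["namespace"]):
        ann.setdefault(e, set()).add(t)
        if isinstance(n, str) and n:
            ns[t] = n
    return ann, ns


def descendant_closure(ont: Ontology, roots: set[str]) -> set[str]:
    """Roots plus all transitive descendants (children point at parents).

    A fixed point: closing an already-closed set changes nothing.
    """
    unknown = set(roots) - ont.terms
    if unknown:
        raise KeyError(f"unknown root terms: {sorted(unknown)}")
    out: set[str] = set()
    for r in roots:
        out.add(r)
        out |= nx.ancestors(ont.graph, r)  # graph ancestors = ontology descendants
    return out


def propagate_annotations(
    ann: dict[str, set[str]], ont: Ontology
) -> dict[str, set[str]]:
    """Up-propagate: each entity inherits all ancestors of its direct terms."""
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for entity, terms in ann.items():
        full: set[str] = set()
        for t in terms:
            if t not in cache:
                cache[t] = ont.ancestors(t) if t in ont.terms else {t}
            full |= cache[t]
        out[entity] = full
    return out


def coannotation_standard(
    ann: dict[str, set[str]],
    ont: Ontology,
    max_annotation_count: int | float | None = None,
    namespace: str = "biological_process",
    candidate_pairs: set[Pair] | None = None,
) -> tuple[PairSet, set[Pair]]:
    """Pairs sharing >= 1 surviving biological-process term after propagation.

    Terms annotated (post up-propagation) to more than ``max_annotation_count``
    proteins are discarded before pair comparison, so near-universal terms do
    not trivially co-annotate everything. The default cutoff is 5% of the
    annotated proteins. The universe is pairs with both proteins annotated to
    >= 1 surviving term.
    """
    if ont.namespace:
        ns_terms = {t for t, n in ont.namespace.items() if n == namespace}
        ann = {e: ts & ns_terms for e, ts in ann.items()}
        ann = {e: ts for e, ts in ann.items() if ts}
    full = propagate_annotations(ann, ont)
    term_counts: dict[str, int] = {}
    for terms in full.values():
        for t in terms:
            term_counts[t] = term_counts.get(t, 0) + 1
    if max_annotation_count is None:
        max_annotation_count = 0.05 * len(full)
    keep = {t for t, c in term_counts.items() if c <= max_annotation_count}
    filtered = {e: ts & keep for e, ts in full.items()}
    filtered = {e: ts for e, ts in filtered.items() if ts}
    annotated = set(filtered)
    if candidate_pairs is None:
        from itertools import combinations

        candidate_pairs = set(combinations(sorted(annotated), 2))
    universe = {p for p in candidate_pairs if p[0] in annotated and p[1] in annotated}
    std = {p for p in universe if filtered[p[0]] & filtered[p[1]]}
    return PairSet("coannotation", std), universe


# --------------------------------------------------------------------------
# SLIM classification of complexes
# --------------------------------------------------------------------------


def classify_complexes_by_slim(
    ds: ComplexDataset,
    ont: Ontology,
    slim_roots: set[str],
    ann: dict[str, set[str]] | None = None,
) -> tuple[dict[str, int], int]:
    """Count complexes annotated to each SLIM root or any of its descendants.

    Complex-level GO annotations come from the records themselves (ComplexTab
    carries them) unless ``ann`` supplies a complex_id -> term map. A complex
    annotated to two roots counts once in the overall total and once under
    each root. Returns per-root counts and the number of complexes matching
    at least one root.
    """
    closures = {r: descendant_closure(ont, {r}) for r in slim_roots}
    per_root = {r: 0 for r in slim_roots}
    overall = 0
    for rec in ds.records:
        terms = ann.get(rec.complex_id, set()) if ann is not None else rec.annotations
        hit_any = False
        for r, closure in closures.items():
            if terms & closure:
                per_root[r] += 1
                hit_any = True
        if hit_any:
            overall += 1
    return per_root, overall
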