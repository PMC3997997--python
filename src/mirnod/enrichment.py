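"""Hypergeometric gene-set enrichment of candidates' exclusive target genes.

Given the union of the candidate miRNAs' exclusively regulated genes as the
query, each gene set (pathway, disease signature, GO term, ...) in a GMT
collection is scored with the upper-tail hypergeometric probability
P(X ≥ overlap) of drawing at least the observed overlap when |query ∩
universe| genes are sampled without replacement from the universe. The
universe defaults to the union of all collection genes (annotated-universe
convention) and can be overridden, e.g. with the interaction database's gene
space. Query genes absent from the universe are dropped from the draw count
and tallied in a warning counter.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .nod import NODResult

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "load_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "enrich_candidates",
    "enrichment_to_frame",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe (GMT-backed)."""

    sets: dict[str, tuple[str, frozenset[str]]]   # set_id -> (name, genes)
    universe: frozenset[str]
    n_dropped: int = 0   # genes removed from sets for lying outside the universe

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, frozenset[str]]] = {}
        dropped = 0
        for sid, (name, genes) in self.sets.items():
            inside = frozenset(g for g in genes if g in self.universe)
            dropped += len(genes) - len(inside)
            if inside:
                cleaned[sid] = (name, inside)
        self.sets = cleaned
        self.n_dropped += dropped
        if dropped:
            warnings.warn(
                f"dropped {dropped} set genes outside the universe", stacklevel=2
            )


@dataclass
class EnrichmentResult:
    set_id: str
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float
    overlap_genes: frozenset[str]
    significant: bool


def load_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (set_id <TAB> description <TAB> gene ...).

    The universe defaults to the union of all set genes. A line with fewer
    than three fields, or an empty file, raises a ValueError with the line
    number.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with io.open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            sid, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {sid!r} is empty")
            sets[sid] = (name, genes)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    if universe is None:
        uni = frozenset().union(*(g for _, g in sets.values()))
    else:
        uni = frozenset(universe)
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(collection.sets):
            name, genes = collection.sets[sid]
            fh.write("\t".join([sid, name, *sorted(genes)]) + "\n")


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a query gene set.

    For each set: population = |universe|, successes = |set|, draws =
    |query ∩ universe|; P = P(X ≥ overlap). Results are sorted by P
    ascending (ties by set_id); ``significant`` flags raw P < alpha, and a
    Benjamini–Hochberg column is always attached for transparency.
    """
    q_all = frozenset(query)
    q = q_all & collection.universe
    if q_all and not q:
        warnings.warn("query is disjoint from the universe; all results trivial",
                      stacklevel=2)
    n_outside = len(q_all) - len(q)
    if n_outside:
        warnings.warn(f"{n_outside} query genes outside the universe were dropped",
                      stacklevel=2)
    M = len(collection.universe)
    N = len(q)
    results: list[EnrichmentResult] = []
    for sid, (name, genes) in collection.sets.items():
        overlap_genes = q & genes
        k = len(overlap_genes)
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        p = min(max(p, 0.0), 1.0)
        results.append(
            EnrichmentResult(sid, name, k, K, N, M, p, float("nan"),
                             frozenset(overlap_genes), p < alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.set_id))
    n = len(results)
    if n:
        qv = 1.0
        adj = [r.p_value * n / (i + 1) for i, r in enumerate(results)]
        for i in range(n - 1, -1, -1):
            qv = min(qv, adj[i])
            results[i].q_value = qv
    return results


def enrich_candidates(
    nod_results: "Mapping[str, NODResult] | Sequence[NODResult]",
    collections: Mapping[str, GeneSetCollection],
    alpha: float = 0.05,
) -> dict[str, list[EnrichmentResult]]:
    """Enrich the union of candidates' exclusive targets in each collection.

    Exclusive-target sets are disjoint across miRNAs by construction, so the
    query size is the sum of the candidates' NOD values.
    """
    if isinstance(nod_results, Mapping):
        nods = list(nod_results.values())
    else:
        nods = list(nod_results)
    if not nods:
        raise ValueError("no candidate NOD results supplied")
    query: set[str] = set()
    for r in nods:
        query |= r.exclusive_targets
    return {
        name: hypergeom_enrich(query, coll, alpha=alpha)
        for name, coll in collections.items()
    }


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
            "overlap_genes": [";".join(sorted(r.overlap_genes)) for r in results],
        }
    )
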