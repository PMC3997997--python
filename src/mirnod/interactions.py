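"""Union miRNA–mRNA interaction database.

A single interaction database is assembled from several per-source tables of
miRNA→gene pairs. Sources are either experimentally *validated* (e.g.
reporter-assay curated collections) or *predicted* (sequence/expression-based
target prediction). Validated pairs are taken as-is; a predicted pair enters
the union only when it is supported by at least ``min_predicted_support``
distinct prediction sources, which suppresses the high false-positive rate of
any single predictor.

Identifier policy: miRNA names are lower-cased (the species prefix, e.g.
``hsa-``, is preserved) and gene symbols upper-cased, so joins across sources
are deterministic without an external alias service. Star/arm variants such
as ``mir-193b*`` remain distinct identifiers.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "VALIDATED",
    "PREDICTED",
    "InteractionRecord",
    "InteractionDB",
    "DBSummary",
    "load_source_table",
    "build_union_db",
    "db_summary",
    "normalize_mirna",
    "normalize_gene",
]

VALIDATED = "validated"
PREDICTED = "predicted"
_EVIDENCE_VALUES = (VALIDATED, PREDICTED)


def normalize_mirna(name: str) -> str:
    """Canonical miRNA identifier: stripped and lower-cased."""
    return name.strip().lower()


def normalize_gene(name: str) -> str:
    """Canonical gene symbol: stripped and upper-cased."""
    return name.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One provenance-tagged miRNA→gene interaction."""

    mirna_id: str
    gene_id: str
    source: str
    evidence: str

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.gene_id:
            raise ValueError("mirna_id and gene_id must be non-empty")
        if self.evidence not in _EVIDENCE_VALUES:
            raise ValueError(
                f"evidence must be one of {_EVIDENCE_VALUES}, got {self.evidence!r}"
            )


class DBSummary(NamedTuple):
    n_edges: int
    n_mirnas: int
    n_genes: int


def load_source_table(
    path: str | Path,
    source_name: str,
    evidence: str,
    has_header: bool = False,
) -> list[InteractionRecord]:
    """Read a tab-separated miRNA/gene table into interaction records.

    Lines starting with ``#`` and blank lines are skipped; duplicate
    (miRNA, gene) rows collapse to a single record. Rows with fewer than two
    columns raise a :class:`ValueError` naming the offending line number.
    """
    if evidence not in _EVIDENCE_VALUES:
        raise ValueError(f"evidence must be one of {_EVIDENCE_VALUES}")
    path = Path(path)
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    with io.open(path, "r", encoding="utf-8") as fh:
        skipped_header = not has_header
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not skipped_header:
                skipped_header = True
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            key = (normalize_mirna(fields[0]), normalize_gene(fields[1]))
            if key in seen:
                continue
            seen.add(key)
            records.append(InteractionRecord(key[0], key[1], source_name, evidence))
    return records


@dataclass
class InteractionDB:
    """Deduplicated bipartite miRNA→gene network with per-edge provenance.

    ``edges`` maps each (miRNA, gene) pair to the non-empty tuple of
    (source, evidence) pairs that contributed it. ``mirna_index`` and
    ``gene_index`` are exact transposes of each other.
    """

    edges: dict[tuple[str, str], tuple[tuple[str, str], ...]]
    mirna_index: dict[str, set[str]] = field(default_factory=dict)
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mirna_index and not self.gene_index:
            self._rebuild_indices()

    def _rebuild_indices(self) -> None:
        mi: dict[str, set[str]] = defaultdict(set)
        gi: dict[str, set[str]] = defaultdict(set)
        for m, g in self.edges:
            mi[m].add(g)
            gi[g].add(m)
        self.mirna_index = dict(mi)
        self.gene_index = dict(gi)

    def targets(self, mirna_id: str) -> set[str]:
        return self.mirna_index.get(mirna_id, set())

    def regulators(self, gene_id: str) -> set[str]:
        return self.gene_index.get(gene_id, set())

    @property
    def mirnas(self) -> set[str]:
        return set(self.mirna_index)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_index)

    def summary(self) -> DBSummary:
        return DBSummary(len(self.edges), len(self.mirna_index), len(self.gene_index))

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, path: str | Path) -> None:
        """Write the union DB as a TSV that :meth:`read_tsv` can load back."""
        path = Path(path)
        with io.open(path, "w", encoding="utf-8") as fh:
            fh.write("mirna\tgene\tn_validated_sources\tn_predicted_sources\tsources\n")
            for (m, g) in sorted(self.edges):
                prov = self.edges[(m, g)]
                n_val = sum(1 for _, ev in prov if ev == VALIDATED)
                n_pred = sum(1 for _, ev in prov if ev == PREDICTED)
                joined = ";".join(f"{src}:{ev}" for src, ev in prov)
                fh.write(f"{m}\t{g}\t{n_val}\t{n_pred}\t{joined}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionDB":
        path = Path(path)
        edges: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {}
        with io.open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("mirna\tgene"):
                raise ValueError(f"{path}: not a union-DB TSV (bad header)")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ValueError(f"{path}: line {lineno}: expected 5 columns")
                m, g = fields[0], fields[1]
                prov = tuple(
                    (src, ev)
                    for src, _, ev in (s.partition(":") for s in fields[4].split(";"))
                )
                edges[(m, g)] = prov
        return cls(edges=edges)


def build_union_db(
    validated_tables: Sequence[Iterable[InteractionRecord]],
    predicted_tables: Sequence[Iterable[InteractionRecord]],
    min_predicted_support: int = 2,
) -> InteractionDB:
    """Merge validated and predicted interaction tables into the union DB.

    An edge is kept iff it occurs in at least one validated source OR in at
    least ``min_predicted_support`` *distinct* predicted sources. Distinctness
    is by source name, not by row. A pair backed by one validated plus one
    predicted source is kept (validation suffices); its provenance records
    both contributions.
    """
    if min_predicted_support < 1:
        raise ValueError("min_predicted_support must be >= 1")

    provenance: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    validated_pairs: set[tuple[str, str]] = set()
    predicted_sources: dict[tuple[str, str], set[str]] = defaultdict(set)

    for table in validated_tables:
        for rec in table:
            key = (rec.mirna_id, rec.gene_id)
            if (rec.source, VALIDATED) not in provenance[key]:
                provenance[key].append((rec.source, VALIDATED))
            validated_pairs.add(key)
    for table in predicted_tables:
        for rec in table:
            key = (rec.mirna_id, rec.gene_id)
            if (rec.source, PREDICTED) not in provenance[key]:
                provenance[key].append((rec.source, PREDICTED))
            predicted_sources[key].add(rec.source)

    edges: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {}
    for key, prov in provenance.items():
        if key in validated_pairs or len(predicted_sources.get(key, ())) >= min_predicted_support:
            edges[key] = tuple(prov)
    return InteractionDB(edges=edges)


def db_summary(db: InteractionDB) -> DBSummary:
    """Edge / miRNA / gene counts of the union database."""
    return db.summary()
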