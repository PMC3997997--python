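"""Synthetic study inputs with planted ground truth.

Generates every input the biomarker pipeline consumes — per-source
miRNA–target tables, a case/control expression matrix, a PPI edge list and
GMT gene-set collections — together with a :class:`SyntheticTruth` record of
what was planted, so end-to-end recovery can be measured.

Default dimensions mirror a serum-miRNA microarray study of sepsis: a union
regulatory network of 641 miRNAs × 7706 genes at ~51 targets per miRNA, an
expression matrix of 556 miRNAs over 8 sepsis and 8 control samples, and ten
planted biomarkers whose exclusive-target counts follow the profile
53, 35, 33, 20, 15, 11, 11, 11, 10, 8 (207 exclusively regulated genes in
total), two of them down-regulated. Baseline intensities are log-normal with
multiplicative log-normal noise, so linear fold changes are well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .interactions import (
    PREDICTED,
    VALIDATED,
    InteractionRecord,
)

__all__ = [
    "PlantedBiomarker",
    "SyntheticTruth",
    "DEFAULT_PLANTED",
    "gen_interaction_network",
    "gen_expression",
    "gen_ppi",
    "gen_gene_sets",
    "write_bundle",
]


@dataclass(frozen=True)
class PlantedBiomarker:
    mirna_id: str
    direction: str          # "up" | "down"
    effect: float           # multiplicative effect on case means (>0)
    planted_nod: int


# Ten planted biomarkers emulating a sepsis serum-miRNA panel: exclusive-target
# counts 53..8 (sum 207), two down-regulated, four-fold expression effects.
DEFAULT_PLANTED: tuple[PlantedBiomarker, ...] = (
    PlantedBiomarker("hsa-let-7b", "up", 4.0, 53),
    PlantedBiomarker("hsa-mir-16", "up", 4.0, 35),
    PlantedBiomarker("hsa-mir-15b", "up", 4.0, 33),
    PlantedBiomarker("hsa-mir-146a", "down", 4.0, 20),
    PlantedBiomarker("hsa-mir-210", "up", 4.0, 15),
    PlantedBiomarker("hsa-mir-340", "down", 4.0, 11),
    PlantedBiomarker("hsa-mir-145", "up", 4.0, 11),
    PlantedBiomarker("hsa-mir-484", "up", 4.0, 11),
    PlantedBiomarker("hsa-mir-324-3p", "up", 4.0, 10),
    PlantedBiomarker("hsa-mir-486-5p", "up", 4.0, 8),
)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated artifact (or a merged bundle)."""

    seed: int
    planted_biomarkers: list[PlantedBiomarker] = field(default_factory=list)
    planted_nods: dict[str, int] = field(default_factory=dict)          # all miRNAs
    gene_regulator_counts: dict[str, int] = field(default_factory=dict)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    ppi_degrees: dict[str, int] = field(default_factory=dict)
    planted_set_id: str | None = None

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["decoy_pairs"] = [list(p) for p in self.decoy_pairs]
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["planted_biomarkers"] = [PlantedBiomarker(**b) for b in d["planted_biomarkers"]]
        d["decoy_pairs"] = [tuple(p) for p in d["decoy_pairs"]]
        return cls(**d)


def _default_mirna_ids(n: int) -> list[str]:
    return [f"hsa-mir-s{i:04d}" for i in range(n)]


def _default_gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def gen_interaction_network(
    n_mirnas: int,
    n_genes: int,
    mean_targets: float = 8.0,
    exclusive_fraction: float = 0.1,
    hub_mirnas: Mapping[str, int] | None = None,
    seed: int = 0,
    n_validated_sources: int = 3,
    n_predicted_sources: int = 3,
    decoy_fraction: float = 0.05,
    mirna_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> tuple[list[list[InteractionRecord]], list[list[InteractionRecord]], SyntheticTruth]:
    """Bipartite regulator→target network split across source tables.

    Every intended edge is routed either through one validated source or
    through ≥2 distinct predicted sources, so rebuilding the union under the
    ≥2-predicted-support rule reconstructs the intended network exactly.
    ``decoy_fraction`` adds extra pairs carried by a *single* predicted
    source only — they must be filtered out by the consensus rule. Each
    miRNA's planted NOD (its count of single-regulator target genes) is
    recorded in the truth; ``hub_mirnas`` pins the exclusive-target count of
    selected miRNAs (boosted biomarkers).
    """
    if not (0.0 <= exclusive_fraction <= 1.0):
        raise ValueError("exclusive_fraction must be in [0, 1]")
    if n_validated_sources < 3 or n_predicted_sources < 3:
        raise ValueError("need >= 3 validated and >= 3 predicted sources")
    rng = np.random.default_rng(seed)
    mids = list(mirna_ids) if mirna_ids is not None else _default_mirna_ids(n_mirnas)
    gids = list(gene_ids) if gene_ids is not None else _default_gene_ids(n_genes)
    if len(mids) != n_mirnas or len(gids) != n_genes:
        raise ValueError("id list lengths must match n_mirnas / n_genes")
    hubs = dict(hub_mirnas or {})
    unknown_hubs = sorted(set(hubs) - set(mids))
    if unknown_hubs:
        raise ValueError(f"hub miRNAs not in the miRNA id list: {unknown_hubs}")

    # out-degrees and exclusive-target counts
    degrees = 1 + rng.poisson(max(mean_targets - 1.0, 0.0), size=n_mirnas)
    n_excl = rng.binomial(degrees, exclusive_fraction)
    for i, m in enumerate(mids):
        if m in hubs:
            n_excl[i] = hubs[m]
            degrees[i] = max(degrees[i], n_excl[i])
    if n_mirnas == 1:
        # a single regulator makes every target exclusive
        n_excl[0] = degrees[0]
    if int(n_excl.sum()) > n_genes:
        raise ValueError(
            f"infeasible: {int(n_excl.sum())} exclusive genes demanded, "
            f"only {n_genes} genes available"
        )

    gene_order = list(gids)
    rng.shuffle(gene_order)
    edges: dict[str, set[str]] = {m: set() for m in mids}   # gene -> regulators
    regulators: dict[str, set[str]] = {}

    def add_edge(m: str, g: str) -> None:
        edges[m].add(g)
        regulators.setdefault(g, set()).add(m)

    pos = 0
    exclusive_of: dict[str, list[str]] = {}
    for i, m in enumerate(mids):
        mine = gene_order[pos : pos + int(n_excl[i])]
        pos += int(n_excl[i])
        exclusive_of[m] = mine
        for g in mine:
            add_edge(m, g)
    shared_pool = gene_order[pos:]

    if n_mirnas >= 2 and shared_pool:
        pool = np.array(shared_pool)
        for i, m in enumerate(mids):
            s = int(degrees[i] - n_excl[i])
            if s <= 0:
                continue
            s = min(s, len(pool))
            picks = rng.choice(pool, size=s, replace=False)
            for g in picks:
                add_edge(m, str(g))
        # genes in the shared pool with a single regulator would become
        # accidental exclusives; give each a second regulator
        for g in shared_pool:
            regs = regulators.get(g)
            if regs is not None and len(regs) == 1:
                (owner,) = regs
                others = [m for m in mids if m != owner]
                add_edge(str(rng.choice(others)), g)

    intended: list[tuple[str, str]] = sorted(
        (m, g) for m, gs in edges.items() for g in gs
    )

    # route each edge through validated or predicted sources
    val_names = [f"validated_{chr(ord('a') + i)}" for i in range(n_validated_sources)]
    pred_names = [f"predicted_{chr(ord('a') + i)}" for i in range(n_predicted_sources)]
    val_tables: dict[str, list[InteractionRecord]] = {s: [] for s in val_names}
    pred_tables: dict[str, list[InteractionRecord]] = {s: [] for s in pred_names}
    for m, g in intended:
        if rng.random() < 0.5:
            k = 1 if rng.random() < 0.8 else 2
            for s in rng.choice(val_names, size=k, replace=False):
                val_tables[str(s)].append(InteractionRecord(m, g, str(s), VALIDATED))
        else:
            k = 2 if rng.random() < 0.8 else 3
            k = min(k, n_predicted_sources)
            for s in rng.choice(pred_names, size=k, replace=False):
                pred_tables[str(s)].append(InteractionRecord(m, g, str(s), PREDICTED))

    # decoys: unsupported single-source predictions, excluded by the ≥2 rule
    intended_set = set(intended)
    n_decoys = int(round(decoy_fraction * len(intended)))
    decoys: list[tuple[str, str]] = []
    seen_decoys: set[tuple[str, str]] = set()
    attempts = 0
    while len(decoys) < n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        pair = (str(rng.choice(mids)), str(rng.choice(gids)))
        if pair in intended_set or pair in seen_decoys:
            continue
        seen_decoys.add(pair)
        decoys.append(pair)
        s = str(rng.choice(pred_names))
        pred_tables[s].append(InteractionRecord(pair[0], pair[1], s, PREDICTED))

    truth = SyntheticTruth(
        seed=seed,
        planted_nods={m: len(exclusive_of[m]) for m in mids},
        gene_regulator_counts={g: len(r) for g, r in regulators.items()},
        decoy_pairs=decoys,
    )
    return list(val_tables.values()), list(pred_tables.values()), truth


def gen_expression(
    n_mirnas: int = 556,
    n_case: int = 8,
    n_control: int = 8,
    planted: Sequence[PlantedBiomarker] = (),
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    mirna_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Case/control intensity matrix with planted differential biomarkers.

    Each row's baseline intensity is 2**N(baseline_log2_mean, baseline_log2_sd);
    cells receive multiplicative noise 2**N(0, noise_sd). Planted rows have
    their case-group cells multiplied (up) or divided (down) by the effect
    multiplier. A fixed seed gives a bit-identical matrix.
    """
    rng = np.random.default_rng(seed)
    mids = list(mirna_ids) if mirna_ids is not None else _default_mirna_ids(n_mirnas)
    if len(mids) != n_mirnas:
        raise ValueError("mirna_ids length must equal n_mirnas")
    planted_ids = [b.mirna_id for b in planted]
    if len(set(planted_ids)) != len(planted_ids):
        raise ValueError("duplicate planted biomarker ids")
    missing = sorted(set(planted_ids) - set(mids))
    if missing:
        raise ValueError(f"planted ids not among matrix rows: {missing}")
    for b in planted:
        if b.effect <= 0:
            raise ValueError(f"effect multiplier must be > 0 for {b.mirna_id}")
        if b.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down' for {b.mirna_id}")

    n_samples = n_case + n_control
    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_mirnas)
    noise = 2.0 ** rng.normal(0.0, noise_sd, size=(n_mirnas, n_samples))
    values = baseline[:, None] * noise
    row_of = {m: i for i, m in enumerate(mids)}
    for b in planted:
        i = row_of[b.mirna_id]
        factor = b.effect if b.direction == "up" else 1.0 / b.effect
        values[i, :n_case] *= factor

    samples = [f"sepsis_{j + 1}" for j in range(n_case)] + [
        f"normal_{j + 1}" for j in range(n_control)
    ]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=mids, columns=samples),
        sample_labels=labels,
    )
    truth = SyntheticTruth(seed=seed, planted_biomarkers=list(planted))
    return matrix, truth


def gen_ppi(
    gene_ids: Sequence[str],
    mean_degree: float = 4.0,
    model: str = "erdos_renyi",
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Undirected simple PPI graph over a gene namespace."""
    n = len(gene_ids)
    if mean_degree >= n:
        raise ValueError("mean_degree must be below the number of genes")
    if model == "erdos_renyi":
        p = mean_degree / max(n - 1, 1)
        g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    elif model == "scale_free":
        m = max(1, int(round(mean_degree / 2.0)))
        g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    else:
        raise ValueError(f"unknown PPI model {model!r}")
    g = nx.relabel_nodes(g, {i: gene_ids[i] for i in range(n)})
    truth = SyntheticTruth(seed=seed, ppi_degrees={v: int(d) for v, d in g.degree()})
    return g, truth


def gen_gene_sets(
    universe: Sequence[str],
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    planted_targets: Sequence[str] = (),
    odds_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Gene-set collection with one set oversampling given target genes.

    The designated planted set samples its members with weight
    ``odds_ratio`` for genes in ``planted_targets`` and 1 otherwise
    (weighted sampling without replacement); at odds_ratio 1 it is
    indistinguishable from the background sets.
    """
    lo, hi = set_size_range
    uni = list(dict.fromkeys(universe))
    if hi > len(uni):
        raise ValueError("set sizes exceed the universe size")
    if lo < 1 or lo > hi:
        raise ValueError("invalid set_size_range")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    targets = set(planted_targets) & set(uni)
    if planted_targets and not targets:
        raise ValueError("planted targets are disjoint from the universe")
    rng = np.random.default_rng(seed)
    uni_arr = np.array(uni)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted_id = "set_planted"
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i == 0 and planted_targets:
            w = np.where(np.isin(uni_arr, list(targets)), odds_ratio, 1.0)
            # weighted sampling without replacement via exponential keys
            keys = rng.exponential(1.0, size=len(uni_arr)) / w
            members = uni_arr[np.argsort(keys)[:size]]
            sets[planted_id] = ("planted enriched set", frozenset(map(str, members)))
        else:
            members = rng.choice(uni_arr, size=size, replace=False)
            sets[f"set_{i:04d}"] = (f"background set {i}", frozenset(map(str, members)))
    collection = GeneSetCollection(sets=sets, universe=frozenset(uni))
    truth = SyntheticTruth(
        seed=seed, planted_set_id=planted_id if planted_targets else None
    )
    return collection, truth


# --------------------------------------------------------------------------
# full input bundle


def write_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_mirnas_db: int = 641,
    n_genes: int = 7706,
    n_mirnas_expr: int = 556,
    mean_targets: float = 51.0,
    exclusive_fraction: float = 0.02,
    planted: Sequence[PlantedBiomarker] = DEFAULT_PLANTED,
    noise_sd: float = 0.5,
    ppi_mean_degree: float = 10.0,
    ppi_coverage: float = 0.75,
    n_gene_sets: int = 50,
    gene_set_size_range: tuple[int, int] = (20, 200),
    enrichment_odds_ratio: float = 8.0,
) -> SyntheticTruth:
    """Generate and write a complete, coherent pipeline input bundle.

    Writes per-source interaction TSVs, an expression matrix + labels, a PPI
    edge list covering ``ppi_coverage`` of the gene namespace, two GMT
    collections (one with a set enriched for the planted biomarkers'
    exclusive targets), a ready-to-run ``config.yaml`` and ``truth.json``.
    Sub-generators draw child seeds from one root RNG so the whole bundle is
    a deterministic function of ``seed``.
    """
    out = Path(out_dir)
    (out / "sources").mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    child = lambda: int(root.integers(0, 2**31 - 1))  # noqa: E731

    mids = _default_mirna_ids(n_mirnas_db)
    for i, b in enumerate(planted):
        mids[i] = b.mirna_id
    gids = _default_gene_ids(n_genes)
    hubs = {b.mirna_id: b.planted_nod for b in planted}

    val_tables, pred_tables, net_truth = gen_interaction_network(
        n_mirnas_db,
        n_genes,
        mean_targets=mean_targets,
        exclusive_fraction=exclusive_fraction,
        hub_mirnas=hubs,
        seed=child(),
        mirna_ids=mids,
        gene_ids=gids,
    )
    source_specs = []
    for tables, evidence in ((val_tables, VALIDATED), (pred_tables, PREDICTED)):
        for table in tables:
            name = table[0].source if table else f"empty_{evidence}"
            p = out / "sources" / f"{name}.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("# mirna\tgene\n")
                for rec in table:
                    fh.write(f"{rec.mirna_id}\t{rec.gene_id}\n")
            source_specs.append({"path": str(p), "name": name, "evidence": evidence})

    expr_ids = mids[:n_mirnas_expr]
    matrix, expr_truth = gen_expression(
        n_mirnas=n_mirnas_expr,
        planted=planted,
        noise_sd=noise_sd,
        seed=child(),
        mirna_ids=expr_ids,
    )
    matrix.write_tsv(out / "expression.tsv", out / "labels.tsv")

    n_ppi_genes = int(round(ppi_coverage * n_genes))
    ppi_gene_pool = list(gids)
    np.random.default_rng(child()).shuffle(ppi_gene_pool)
    ppi_genes = ppi_gene_pool[:n_ppi_genes]
    ppi, ppi_truth = gen_ppi(ppi_genes, mean_degree=ppi_mean_degree, seed=child())
    with open(out / "ppi.tsv", "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in ppi.edges()):
            fh.write(f"{a}\t{b}\n")

    # exclusive targets of the planted hubs, for the enriched pathway set
    planted_exclusive = [
        g
        for g, cnt in net_truth.gene_regulator_counts.items()
        if cnt == 1
    ]
    # restrict to genes whose single regulator is a planted biomarker
    planted_ids = {b.mirna_id for b in planted}
    single_reg_of: dict[str, str] = {}
    for table in val_tables + pred_tables:
        for rec in table:
            if net_truth.gene_regulator_counts.get(rec.gene_id) == 1:
                single_reg_of[rec.gene_id] = rec.mirna_id
    planted_exclusive = sorted(
        g for g, m in single_reg_of.items() if m in planted_ids
    )

    pathways, gs_truth = gen_gene_sets(
        gids,
        n_sets=n_gene_sets,
        set_size_range=gene_set_size_range,
        planted_targets=planted_exclusive,
        odds_ratio=enrichment_odds_ratio,
        seed=child(),
    )
    diseases, _ = gen_gene_sets(
        gids,
        n_sets=max(n_gene_sets // 2, 2),
        set_size_range=gene_set_size_range,
        seed=child(),
    )
    from .enrichment import write_gmt

    write_gmt(pathways, out / "pathways.gmt")
    write_gmt(diseases, out / "diseases.gmt")

    truth = SyntheticTruth(
        seed=seed,
        planted_biomarkers=list(planted),
        planted_nods=net_truth.planted_nods,
        gene_regulator_counts=net_truth.gene_regulator_counts,
        decoy_pairs=net_truth.decoy_pairs,
        ppi_degrees=ppi_truth.ppi_degrees,
        planted_set_id=gs_truth.planted_set_id,
    )
    truth.to_json(out / "truth.json")

    config = {
        "seed": seed,
        "sources": source_specs,
        "expression": str(out / "expression.tsv"),
        "labels": str(out / "labels.tsv"),
        "ppi": str(out / "ppi.tsv"),
        "collections": [
            {"name": "pathways", "path": str(out / "pathways.gmt")},
            {"name": "diseases", "path": str(out / "diseases.gmt")},
        ],
        "thresholds": {
            "alpha_de": 0.05,
            "fc_threshold": 2.0,
            "alpha_nod": 0.05,
            "alpha_enrich": 0.05,
            "auc_report_threshold": 0.90,
        },
        "options": {
            "bh_de": False,
            "bh_enrich": False,
            "universe": "collection",
            "min_predicted_support": 2,
            "nod_reference": "db",
        },
        "out_dir": str(out / "run"),
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return truth
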