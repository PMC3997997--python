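"""End-to-end biomarker discovery pipeline.

Stages, in order: build the union interaction database → select
differentially expressed miRNAs (t-test + fold change) → rank them by NOD
and keep those whose NOD is significantly above the population level →
per-candidate ROC/AUC → gene-set enrichment of the pooled exclusive targets
→ per-candidate protein-interaction subnetworks. Every stage writes a plain
TSV into the run directory, with a manifest JSON tying them together, so
each intermediate is auditable. Identical config + inputs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as de
from . import interactions as ia
from . import nod as nodm
from . import pin as pinm
from . import roc as rocm

__all__ = [
    "PipelineConfig",
    "BiomarkerReport",
    "PipelineError",
    "ConfigError",
    "load_config",
    "validate_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_DEFAULT_THRESHOLDS = {
    "alpha_de": 0.05,
    "fc_threshold": 2.0,
    "alpha_nod": 0.05,
    "alpha_enrich": 0.05,
    "auc_report_threshold": 0.90,
}
_DEFAULT_OPTIONS = {
    "bh_de": False,
    "bh_enrich": False,
    "universe": "collection",       # or "db"
    "min_predicted_support": 2,
    "nod_reference": "db",          # or "candidates"
    "include_n1_edges": False,
    "plots": False,
}
_KNOWN_KEYS = {
    "seed", "sources", "expression", "labels", "ppi", "collections",
    "thresholds", "options", "out_dir",
}


@dataclass
class PipelineConfig:
    sources: list[dict[str, str]]               # {path, name, evidence}
    expression: str
    labels: str
    ppi: str
    collections: list[dict[str, str]]           # {name, path}
    out_dir: str
    seed: int = 0
    thresholds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    options: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULT_OPTIONS))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class BiomarkerReport:
    rows: pd.DataFrame          # one row per final candidate, NOD-descending
    summary: dict[str, Any]
    config_hash: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "summary": self.summary,
                    "rows": self.rows.to_dict(orient="records"),
                },
                indent=1,
                sort_keys=True,
            )
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse + validate a YAML config, raising :class:`ConfigError` on problems."""
    cfg, errors, _ = validate_config(path)
    if errors:
        raise ConfigError(errors)
    assert cfg is not None
    return cfg


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str], list[str]]:
    """Validate a config file, collecting *all* errors and warnings at once."""
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:  # unparseable file
        return None, [f"cannot parse config: {exc}"], []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"], []

    for key in raw:
        if key not in _KNOWN_KEYS:
            warnings_.append(f"unknown config key {key!r} ignored")

    for key in ("sources", "expression", "labels", "ppi", "out_dir"):
        if key not in raw:
            errors.append(f"missing required key {key!r}")

    sources = raw.get("sources", [])
    if not isinstance(sources, list) or (
        "sources" in raw and not sources
    ):
        errors.append("'sources' must be a non-empty list of {path,name,evidence}")
        sources = []
    for i, s in enumerate(sources):
        for k in ("path", "name", "evidence"):
            if k not in s:
                errors.append(f"sources[{i}] missing {k!r}")
        if s.get("evidence") not in (ia.VALIDATED, ia.PREDICTED):
            errors.append(f"sources[{i}] has invalid evidence {s.get('evidence')!r}")
        if "path" in s and not Path(s["path"]).exists():
            errors.append(f"sources[{i}] path does not exist: {s['path']}")

    for key in ("expression", "labels", "ppi"):
        if key in raw and not Path(str(raw[key])).exists():
            errors.append(f"{key} path does not exist: {raw[key]}")

    collections = raw.get("collections", [])
    for i, c in enumerate(collections):
        if "name" not in c or "path" not in c:
            errors.append(f"collections[{i}] needs 'name' and 'path'")
        elif not Path(c["path"]).exists():
            errors.append(f"collections[{i}] path does not exist: {c['path']}")

    thresholds = dict(_DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds", {}) or {})
    for k in ("alpha_de", "alpha_nod", "alpha_enrich"):
        v = thresholds.get(k)
        if not isinstance(v, (int, float)) or not (0.0 <= v <= 1.0):
            errors.append(f"threshold {k}={v!r} outside [0, 1]")
    if not isinstance(thresholds.get("fc_threshold"), (int, float)) or thresholds["fc_threshold"] < 1:
        errors.append(f"fc_threshold={thresholds.get('fc_threshold')!r} must be >= 1")

    options = dict(_DEFAULT_OPTIONS)
    options.update(raw.get("options", {}) or {})
    if options.get("universe") not in ("collection", "db"):
        errors.append(f"options.universe must be 'collection' or 'db'")
    if options.get("nod_reference") not in ("db", "candidates"):
        errors.append("options.nod_reference must be 'db' or 'candidates'")
    if not isinstance(options.get("min_predicted_support"), int) or options["min_predicted_support"] < 1:
        errors.append("options.min_predicted_support must be an integer >= 1")

    if errors:
        return None, errors, warnings_
    cfg = PipelineConfig(
        sources=sources,
        expression=str(raw["expression"]),
        labels=str(raw["labels"]),
        ppi=str(raw["ppi"]),
        collections=collections,
        out_dir=str(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        thresholds=thresholds,
        options=options,
    )
    return cfg, [], warnings_


def _read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: labels TSV needs 'sample' and 'group' columns")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def run_pipeline(
    config: PipelineConfig,
    log: Callable[[str], None] | None = None,
) -> BiomarkerReport:
    """Execute all stages, writing intermediates into ``config.out_dir``.

    On a stage failure, partial outputs are kept, a ``FAILED`` marker naming
    the stage is written, and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    say = log or (lambda msg: None)
    thr = config.thresholds
    opt = config.options
    stage = "init"
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    try:
        # ---------------------------------------------------- interaction DB
        stage = "interactions"
        val_tables, pred_tables = [], []
        for s in config.sources:
            table = ia.load_source_table(s["path"], s["name"], s["evidence"])
            (val_tables if s["evidence"] == ia.VALIDATED else pred_tables).append(table)
        db = ia.build_union_db(
            val_tables, pred_tables,
            min_predicted_support=int(opt["min_predicted_support"]),
        )
        n_edges, n_mirnas, n_genes = db.summary()
        db.write_tsv(out / "union_db.tsv")
        manifest["stages"][stage] = {
            "out": "union_db.tsv", "n_edges": n_edges,
            "n_mirnas": n_mirnas, "n_genes": n_genes,
        }
        say(f"[interactions] union DB: {n_edges} pairs, {n_mirnas} miRNAs, {n_genes} genes")

        # ------------------------------------------------------ expression DE
        stage = "expression_de"
        label_map = _read_labels(config.labels)
        matrix = de.load_expression(config.expression, label_map)
        de_results = de.select_candidates(
            matrix,
            alpha=float(thr["alpha_de"]),
            fc_threshold=float(thr["fc_threshold"]),
            bh=bool(opt["bh_de"]),
        )
        de_frame = de.de_results_to_frame(de_results)
        de_frame.to_csv(out / "de_table.tsv", sep="\t", index=False)
        de_candidates = [r for r in de_results if r.is_candidate]
        manifest["stages"][stage] = {
            "out": "de_table.tsv",
            "n_tested": len(de_results),
            "n_candidates": len(de_candidates),
        }
        say(f"[expression_de] {len(de_candidates)} / {len(de_results)} miRNAs pass "
            f"p<{thr['alpha_de']} and |FC|>={thr['fc_threshold']}")

        # -------------------------------------------------------------- NOD
        stage = "nod"
        nod_results = nodm.compute_nod(db)
        nod_frame = pd.DataFrame(
            {
                "mirna": list(nod_results),
                "nod": [r.nod for r in nod_results.values()],
                "exclusive_targets": [
                    ";".join(sorted(r.exclusive_targets)) for r in nod_results.values()
                ],
            }
        ).sort_values(["nod", "mirna"], ascending=[False, True])
        nod_frame.to_csv(out / "nod_table.tsv", sep="\t", index=False)
        ranked = nodm.rank_candidates_by_nod(
            de_candidates,
            nod_results,
            alpha_nod=float(thr["alpha_nod"]),
            reference=str(opt["nod_reference"]),
        )
        final = [r for r in ranked if r.significant]
        all_nod_values = [r.nod for r in nod_results.values()]
        comparison = (
            nodm.compare_nod_distributions([r.nod for r in final], all_nod_values)
            if final
            else None
        )
        manifest["stages"][stage] = {
            "out": "nod_table.tsv",
            "n_de_candidates": len(ranked),
            "n_final_candidates": len(final),
        }
        say(f"[nod] {len(final)} / {len(ranked)} DE candidates have NOD "
            f"significance p<{thr['alpha_nod']}")

        # -------------------------------------------------------------- ROC
        stage = "roc"
        label_vec = [matrix.sample_labels[s] for s in matrix.values.columns]
        rocs: list[rocm.ROCResult] = []
        for r in final:
            scores = matrix.values.loc[r.de.mirna_id].to_numpy()
            direction = -1 if r.de.fc_linear < 0 else 1
            roc = rocm.compute_auc(scores, label_vec, direction=direction,
                                   mirna_id=r.de.mirna_id)
            roc.ci_low, roc.ci_high = rocm.auc_confidence_interval(roc)
            rocs.append(roc)
        roc_frame = pd.DataFrame(
            {
                "mirna": [r.mirna_id for r in rocs],
                "auc": [r.auc for r in rocs],
                "ci_low": [r.ci_low for r in rocs],
                "ci_high": [r.ci_high for r in rocs],
                "orientation": [r.orientation for r in rocs],
            }
        )
        roc_frame.to_csv(out / "roc_table.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"out": "roc_table.tsv", "n_curves": len(rocs)}
        say(f"[roc] computed {len(rocs)} ROC curves")

        # -------------------------------------------------------- enrichment
        stage = "enrichment"
        collections: dict[str, enr.GeneSetCollection] = {}
        for c in config.collections:
            universe = db.genes if opt["universe"] == "db" else None
            collections[c["name"]] = enr.load_gmt(c["path"], universe=universe)
        enrich_tables: dict[str, list[enr.EnrichmentResult]] = {}
        if final and collections:
            cand_nods = {r.de.mirna_id: nod_results[r.de.mirna_id] for r in final
                         if r.de.mirna_id in nod_results}
            enrich_tables = enr.enrich_candidates(
                cand_nods, collections, alpha=float(thr["alpha_enrich"])
            )
            for name, results in enrich_tables.items():
                enr.enrichment_to_frame(results).to_csv(
                    out / f"enrichment_{name}.tsv", sep="\t", index=False
                )
        manifest["stages"][stage] = {
            "collections": {
                name: sum(r.significant for r in results)
                for name, results in enrich_tables.items()
            }
        }
        say(f"[enrichment] {len(enrich_tables)} collections analyzed")

        # --------------------------------------------------------------- PIN
        stage = "pin"
        ppi = pinm.load_ppi(config.ppi)
        pin_rows = []
        for r in final:
            pin = pinm.build_pin(
                r.de.mirna_id, r.exclusive_targets, ppi,
                include_n1_edges=bool(opt.get("include_n1_edges", False)),
            )
            pinm.export_pin(pin, out / f"pin_{r.de.mirna_id.replace('/', '_')}")
            pin_rows.append(pinm.pin_summary_row(pin, r.nod))
        pin_frame = pd.DataFrame(pin_rows, columns=["mirna", "nod", "n0", "n1", "n2"])
        pin_frame.to_csv(out / "pin_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"out": "pin_summary.tsv", "n_pins": len(pin_rows)}
        say(f"[pin] built {len(pin_rows)} protein-interaction subnetworks")

        # ------------------------------------------------------------ report
        stage = "report"
        rows = pd.DataFrame(
            {
                "mirna": [r.de.mirna_id for r in final],
                "de_p": [r.de.p_value for r in final],
                "fc_linear": [r.de.fc_linear for r in final],
                "fc_log2": [r.de.fc_log2 for r in final],
                "nod": [r.nod for r in final],
                "nod_p": [r.nod_p for r in final],
                "auc": [r2.auc for r2 in rocs],
                "ci_low": [r2.ci_low for r2 in rocs],
                "ci_high": [r2.ci_high for r2 in rocs],
                "orientation": [r2.orientation for r2 in rocs],
            }
        )
        auc_threshold = float(thr["auc_report_threshold"])
        summary: dict[str, Any] = {
            "n_candidates": len(final),
            "total_exclusive_genes": int(sum(r.nod for r in final)),
            "db_n_edges": n_edges,
            "db_n_mirnas": n_mirnas,
            "db_n_genes": n_genes,
        }
        if rocs:
            auc_summary = rocm.summarize_auc_table(rocs, threshold=auc_threshold)
            summary.update(
                auc_min=auc_summary.auc_min,
                auc_max=auc_summary.auc_max,
                n_auc_at_or_above=auc_summary.n_at_or_above,
                auc_threshold=auc_threshold,
            )
        if comparison is not None:
            summary.update(
                nod_ks_stat=comparison.ks_stat,
                nod_ks_p=comparison.ks_p,
                candidate_nod_median=comparison.group_median,
                population_nod_median=comparison.population_median,
            )
        report = BiomarkerReport(
            rows=rows,
            summary=summary,
            config_hash=config.config_hash(),
            seed=config.seed,
        )
        rows.to_csv(out / "report.tsv", sep="\t", index=False)
        report.to_json(out / "report.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

        if opt.get("plots"):
            stage = "plots"
            from . import plots

            if final:
                plots.nod_comparison_boxplot(
                    [r.nod for r in final], all_nod_values, out / "nod_boxplot.png"
                )
            if rocs:
                plots.roc_panels(rocs, out / "roc_curves.png")
            for name, results in enrich_tables.items():
                plots.enrichment_bars(results[:10], out / f"enrichment_{name}.png")
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
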