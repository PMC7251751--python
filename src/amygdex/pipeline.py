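"""End-to-end orchestration: integrate gene lists, filter by human and
mouse developmental expression, run single-nucleus DE, and overlap DE
genes with the derived candidate sets.

The run is configured from a single YAML file and emits every
intermediate gene set plus a machine-readable report (JSON) and a
human-readable one (TSV).  Percentages are pass / (pass + fail) — genes
without data never count as failures — rounded half-up to one decimal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from . import genesets, human_expression, mouse_atlas, sc_de
from .genesets import GeneSet, ScoredGeneList, ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        return float("nan")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Paths and thresholds for one orchestrated run."""

    list_a: str
    list_b: str
    expression: str
    sample_meta: str
    atlas: str
    snuc_dir: str
    out_dir: str
    keep_categories: tuple[str, ...] = ("S", "1", "2", "3")
    human: human_expression.HumanFilterCriteria = field(
        default_factory=human_expression.HumanFilterCriteria
    )
    mouse: mouse_atlas.AtlasCriteria = field(default_factory=mouse_atlas.AtlasCriteria)
    fdr_cut: float = sc_de.DEFAULT_FDR_CUT
    fc_cut: float = sc_de.DEFAULT_FC_CUT
    min_detect: float = sc_de.DEFAULT_MIN_DETECT
    scale_factor: int = sc_de.DEFAULT_SCALE_FACTOR
    universe: int = genesets.DEFAULT_UNIVERSE
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unsupported config schema_version {version}")
        human = raw.pop("human", {})
        mouse = raw.pop("mouse", {})
        if "structures" in mouse:
            mouse["structures"] = frozenset(mouse["structures"])
        if "ages" in mouse:
            mouse["ages"] = frozenset(mouse["ages"])
        keep = tuple(str(c) for c in raw.pop("keep_categories", ("S", "1", "2", "3")))
        return cls(
            human=human_expression.HumanFilterCriteria(**human),
            mouse=mouse_atlas.AtlasCriteria(**mouse),
            keep_categories=keep,
            **raw,
        )

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # output location is not analysis-relevant
        payload["mouse"]["structures"] = sorted(payload["mouse"]["structures"])
        payload["mouse"]["ages"] = sorted(payload["mouse"]["ages"])
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate_paths(config: PipelineConfig) -> None:
    for name in ("list_a", "list_b", "expression", "sample_meta", "atlas", "snuc_dir"):
        path = Path(getattr(config, name))
        if not path.exists():
            raise ValidationError(f"input path for {name!r} does not exist: {path}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run(config: PipelineConfig) -> dict:
    """Execute integrate -> filter-human -> filter-mouse -> de -> overlap.

    Returns the report dict; every intermediate gene set and table is
    written under ``config.out_dir``.
    """
    _validate_paths(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.digest(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # stage 1: integrate -----------------------------------------------------
    stage = "integrate"
    try:
        list_a = ScoredGeneList.from_tsv(config.list_a)
        list_b = ScoredGeneList.from_tsv(config.list_b)
        set_a = genesets.filter_by_category(list_a, config.keep_categories)
        set_b = genesets.filter_by_category(list_b, config.keep_categories)
        union, inter = genesets.integrate(set_a, set_b)
        union.to_text(out / "integrated_genes.txt")
        overlap = genesets.overlap_test(set_a, set_b, universe=config.universe)
        genesets.write_overlap_report({"list_a_vs_list_b": overlap}, out / "list_overlap.tsv")
    except (ValidationError, OSError) as err:
        raise StageError(stage, str(err)) from err
    report["stages"][stage] = {
        "size_a": len(set_a),
        "size_b": len(set_b),
        "overlap": overlap.overlap,
        "union": len(union),
        "overlap_p_value": overlap.p_value,
    }
    logger.info("integrate: %d + %d -> union %d (overlap %d)",
                len(set_a), len(set_b), len(union), overlap.overlap)

    # stage 2: human expression filter --------------------------------------
    stage = "filter_human"
    try:
        matrix = human_expression.DevExpressionMatrix.from_tsv(
            config.expression, config.sample_meta
        )
        profile = human_expression.summarize_by_period(matrix, config.human.region)
        profile.to_tsv(out / "period_profile.tsv")
        h_pass, h_fail, h_nodata = human_expression.classify_genes(
            union, profile, config.human
        )
        h_pass.to_text(out / "human_expressed_genes.txt")
        human_expression.write_filter_report(
            h_pass, h_fail, h_nodata, out / "human_filter_report.tsv"
        )
        variance_all = human_expression.variance_summary(matrix, None)
        variance_pass = human_expression.variance_summary(matrix, h_pass)
    except (ValidationError, OSError) as err:
        raise StageError(stage, str(err)) from err
    with_data = len(h_pass) + len(h_fail)
    report["stages"][stage] = {
        "input": len(union),
        "no_data": len(h_nodata),
        "pass": len(h_pass),
        "fail": len(h_fail),
        "pass_percent": percent(len(h_pass), with_data),
        "variance_background": variance_all,
        "variance_pass": variance_pass,
    }
    logger.info("filter_human: %d/%d pass (%.1f%%), %d without data",
                len(h_pass), with_data, percent(len(h_pass), with_data), len(h_nodata))

    # stage 3: mouse atlas filter -------------------------------------------
    stage = "filter_mouse"
    try:
        atlas = mouse_atlas.AtlasTable.from_tsv(config.atlas)
        m_pass, m_fail, m_nodata = mouse_atlas.filter_atlas(atlas, h_pass, config.mouse)
        m_pass.to_text(out / "mouse_validated_genes.txt")
        mouse_atlas.write_atlas_report(
            atlas, m_pass, m_fail, m_nodata, config.mouse, out / "mouse_filter_report.tsv"
        )
    except (ValidationError, OSError) as err:
        raise StageError(stage, str(err)) from err
    m_with_data = len(m_pass) + len(m_fail)
    report["stages"][stage] = {
        "input": len(h_pass),
        "no_data": len(m_nodata),
        "pass": len(m_pass),
        "fail": len(m_fail),
        "pass_percent": percent(len(m_pass), m_with_data),
    }
    logger.info("filter_mouse: %d/%d pass (%.1f%%), %d without data",
                len(m_pass), m_with_data, percent(len(m_pass), m_with_data), len(m_nodata))

    # stage 4: single-nucleus DE --------------------------------------------
    stage = "de"
    try:
        dataset = sc_de.SnucDataset.from_mtx_dir(config.snuc_dir)
        spec = sc_de.HurdleModelSpec(min_detect=config.min_detect)
        de_results = sc_de.de_analysis(
            dataset,
            spec=spec,
            fdr_cut=config.fdr_cut,
            fc_cut=config.fc_cut,
            scale_factor=config.scale_factor,
        )
        sc_de.write_de_table(de_results, out / "de_table.tsv")
        events, de_genes = sc_de.de_event_counts(de_results)
    except (ValidationError, OSError) as err:
        raise StageError(stage, str(err)) from err
    per_cluster = {}
    for r in de_results:
        if r.is_de:
            per_cluster[str(r.cluster)] = per_cluster.get(str(r.cluster), 0) + 1
    report["stages"][stage] = {
        "tested": len(de_results),
        "de_events": events,
        "de_genes": de_genes,
        "events_per_cluster": per_cluster,
    }
    logger.info("de: %d events in %d genes", events, de_genes)

    # stage 5: cell-type overlap --------------------------------------------
    stage = "overlap"
    try:
        table = sc_de.celltype_overlap(
            de_results,
            [m_pass, h_pass],
            universe=config.universe,
        )
        table.to_csv(out / "celltype_overlap.tsv", sep="\t", index=False)
    except (ValidationError, OSError) as err:
        raise StageError(stage, str(err)) from err
    de_set = frozenset(r.gene for r in de_results if r.is_de)
    report["stages"][stage] = {
        "de_genes_in_mouse_set": len(de_set & m_pass.symbols),
        "de_genes_in_human_set": len(de_set & h_pass.symbols),
    }

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = ["stage\tkey\tvalue"]
    for stage, payload in report["stages"].items():
        for key, value in payload.items():
            lines.append(f"{stage}\t{key}\t{value}")
    (out / "report.tsv").write_text("\n".join(lines) + "\n")
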