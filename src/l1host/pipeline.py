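"""End-to-end orchestration: annotate -> call -> enrich -> cross-experiment ->
AGO2 -> report.

The report bundle is a JSON file plus TSVs; every statistic in the report
carries its raw 2x2 table and the parameters that produced it, so each
number is recomputable from the emitted intermediate files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ago2 as ago2_mod
from . import cudream as cudream_mod
from .enrichment import build_membership_table, chisq_or
from .expression import call_genes, read_experiment, select_alpha
from .features import FeatureRegistry, run_feature_screen, screen_to_frame
from .intervals import (
    INTRAGENIC, classify_l1_locations, find_flanking_l1s,
    read_genes_bed, read_genes_gff3, read_l1_bed, write_annotated_l1_tsv,
)

logger = logging.getLogger("l1host")

_KNOWN_KEYS = {
    "genes", "genes_format", "l1", "l1_features", "sites", "matrix", "groups",
    "probe_map", "matrix_b", "groups_b", "probe_map_b", "design", "ip_derived",
    "alpha", "test_mode", "overlap_mode", "direction_a", "direction_b",
    "flank_window_bp", "histogram_anchor", "categorical_features",
    "numeric_features", "outdir", "seed",
}


@dataclass
class PipelineConfig:
    """Validated stage parameters and input/output paths."""

    genes: str = None
    genes_format: str = "bed"        # bed | gff3
    l1: str = None
    l1_features: str = None
    sites: str = None
    matrix: str = None
    groups: str = None
    probe_map: str = None
    matrix_b: str = None             # optional second experiment for CU-DREAM
    groups_b: str = None
    probe_map_b: str = None
    design: str = "unpaired"
    ip_derived: bool = False
    alpha: float = None              # override; default from select_alpha
    test_mode: str = "one_sided"
    overlap_mode: str = "overlap"    # intragenic definition: overlap | containment
    direction_a: str = "down"
    direction_b: str = "down"
    flank_window_bp: int = 1000
    histogram_anchor: str = "five_prime"
    categorical_features: tuple = ()
    numeric_features: tuple = ()
    outdir: str = "report"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""


def _require(config, stage, *names):
    for name in names:
        path = getattr(config, name)
        if path is None:
            raise StageError(f"stage {stage}: required input '{name}' not configured")
        if not Path(path).exists():
            raise StageError(f"stage {stage}: input path does not exist: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle to
    ``config.outdir``.  Returns the report dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"parameters": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in dataclasses.asdict(config).items()}}

    # --- annotate ---
    _require(config, "annotate", "genes", "l1")
    genes = (read_genes_gff3(config.genes) if config.genes_format == "gff3"
             else read_genes_bed(config.genes))
    l1s = read_l1_bed(config.l1, config.l1_features)
    try:
        l1s = classify_l1_locations(l1s, genes, mode=config.overlap_mode)
    except Exception as exc:
        raise StageError(f"stage annotate: {exc}") from exc
    write_annotated_l1_tsv(l1s, outdir / "l1_annotated.tsv")
    l1_gene_set = {g for l1 in l1s if l1.location_class == INTRAGENIC for g in l1.host_genes}
    report["annotate"] = {
        "n_l1": len(l1s),
        "n_intragenic": sum(l1.location_class == INTRAGENIC for l1 in l1s),
        "n_intergenic": sum(l1.location_class == "intergenic" for l1 in l1s),
        "n_l1_genes": len(l1_gene_set),
    }
    flanks = find_flanking_l1s(l1s, genes, config.flank_window_bp)
    report["annotate"]["n_flank_assignments"] = len(flanks)

    # --- feature screen ---
    if config.categorical_features or config.numeric_features:
        registry = FeatureRegistry(tuple(config.categorical_features),
                                   tuple(config.numeric_features))
        try:
            screen = run_feature_screen(l1s, registry)
        except Exception as exc:
            raise StageError(f"stage l1-features: {exc}") from exc
        screen_to_frame(screen).to_csv(outdir / "feature_screen.tsv", sep="\t", index=False)
        report["feature_screen"] = {"n_tests": len(screen)}

    # --- expression calls ---
    calls = calls_b = None
    if config.matrix:
        _require(config, "call-expression", "matrix", "groups", "probe_map")
        exp = read_experiment(config.matrix, config.groups, config.probe_map,
                              experiment_id="A", design=config.design,
                              ip_derived=config.ip_derived)
        calls = call_genes(exp, alpha=config.alpha, mode=config.test_mode)
        calls.to_tsv(outdir / "calls_a.tsv")
        report["calls_a"] = {
            "alpha": calls.alpha, "n_genes": len(calls.frame),
            "n_up": int(calls.frame["up"].sum()), "n_down": int(calls.frame["down"].sum()),
        }
    if config.matrix_b:
        _require(config, "call-expression-b", "matrix_b", "groups_b", "probe_map_b")
        exp_b = read_experiment(config.matrix_b, config.groups_b, config.probe_map_b,
                                experiment_id="B", design=config.design,
                                ip_derived=config.ip_derived)
        calls_b = call_genes(exp_b, alpha=config.alpha, mode=config.test_mode)
        calls_b.to_tsv(outdir / "calls_b.tsv")

    # --- enrichment ---
    if calls is not None and l1_gene_set:
        enrich = {}
        for direction in ("up", "down"):
            try:
                table = build_membership_table(calls, l1_gene_set, direction)
            except ValueError as exc:
                raise StageError(f"stage enrich: {exc}") from exc
            enrich[direction] = chisq_or(table).to_dict()
        report["enrichment"] = enrich

    # --- CU-DREAM ---
    if calls is not None and calls_b is not None:
        try:
            cross = cudream_mod.intersect_experiments(
                calls, calls_b, config.direction_a, config.direction_b)
        except cudream_mod.EmptyUniverseError as exc:
            raise StageError(f"stage cudream: {exc}") from exc
        report["cudream"] = cross.to_dict()
        if l1_gene_set:
            try:
                within, outside = cudream_mod.stratified_intersect(
                    calls, calls_b, l1_gene_set, config.direction_a, config.direction_b)
                report["cudream_stratified"] = {
                    "within_l1": within.to_dict(), "outside_l1": outside.to_dict(),
                }
            except cudream_mod.EmptyUniverseError as exc:
                logger.warning("stratified CU-DREAM skipped: %s", exc)

    # --- AGO2 ---
    if config.sites:
        _require(config, "ago2-map", "sites")
        sites = ago2_mod.filter_sites(ago2_mod.read_sites_bed(config.sites))
        report["ago2"] = {"n_sites_after_filter": len(sites)}
        if calls is not None:
            up = calls.regulated("up")
            if up:
                table, assoc = ago2_mod.ago2_l1_association(sites, genes, l1_gene_set, up)
                report["ago2"]["association"] = assoc.to_dict()
        for orientation in ("sense", "antisense"):
            hist = ago2_mod.l1_proximity_histogram(
                sites, l1s, genes, orientation, anchor=config.histogram_anchor)
            hist.to_frame().to_csv(outdir / f"histogram_{orientation}.tsv",
                                   sep="\t", index=False)
            report["ago2"][f"histogram_{orientation}"] = {
                "n_bins": hist.n_bins, "n_anchors": hist.n_anchors,
                "n_sites_in_range": hist.n_sites_in_range,
            }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
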