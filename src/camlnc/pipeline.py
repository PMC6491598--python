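"""End-to-end orchestration: run every analysis stage in dependency order
from one config, writing tables and a deterministic run report.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    DataError,
    concat_samples,
    average_by_tissue,
    read_annotation,
    read_bindings,
    read_expression,
    read_transcripts,
    write_gtf,
    write_tsv,
)
from .identify import (
    IdentificationConfig,
    assign_class_codes,
    classify_biotype,
    filter_lncrna,
)
from .characterize import (
    compare_expression_distributions,
    feature_summary,
    locus_distances,
)
from .tissue_specificity import (
    SpecificityConfig,
    call_specificity,
    specificity_distribution_compare,
    specificity_table,
)
from .coexpression import build_network, degree_summary
from .cerna import cerna_network_export, focal_cerna, pairs_table, shared_mirna_pairs
from .diel_cycling import CyclingConfig, calls_table, classify_overlap, score_matrix

log = logging.getLogger("camlnc")

STAGES = ("identify", "classify", "characterize", "tau", "coexpress", "cerna", "cycling")


@dataclass
class RunConfig:
    """Paths plus per-stage parameter blocks for a full pipeline run."""

    ref: str
    candidates: str
    scores: str
    diel_green: str
    diel_green_samples: str
    diel_white: str
    diel_white_samples: str
    tissues: str
    tissues_samples: str
    bindings: str
    out_dir: str
    seed: int = 0
    r_threshold: float = 0.95
    focal_ids: list[str] = field(default_factory=list)
    identification: IdentificationConfig = field(default_factory=IdentificationConfig)
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)
    cycling: CyclingConfig = field(default_factory=CyclingConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (
            ("identification", IdentificationConfig),
            ("specificity", SpecificityConfig),
            ("cycling", CyclingConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate_paths(self) -> None:
        for name in ("ref", "candidates", "scores", "diel_green", "diel_green_samples",
                     "diel_white", "diel_white_samples", "tissues", "tissues_samples",
                     "bindings"):
            path = getattr(self, name)
            if not path:
                raise DataError(f"run config field '{name}' is empty")
            if not os.path.exists(path):
                raise DataError(f"run config field '{name}': no such file {path}")


def run_all(cfg: RunConfig) -> dict:
    """Run identify -> classify -> characterize -> tau -> coexpress -> cerna
    -> cycling, writing per-stage tables under ``cfg.out_dir`` plus a
    deterministic ``report.json``.  Returns the report."""
    cfg.validate_paths()
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "identification": asdict(cfg.identification),
            "specificity": asdict(cfg.specificity),
            "cycling": asdict(cfg.cycling),
            "r_threshold": cfg.r_threshold,
        },
        "stages": {},
    }

    def out(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    # ---- identify ------------------------------------------------------
    ref = read_annotation(cfg.ref)
    candidates, _ = read_transcripts(cfg.candidates)
    scores = pd.read_csv(cfg.scores, sep="\t")
    green = read_expression(cfg.diel_green, cfg.diel_green_samples)
    white = read_expression(cfg.diel_white, cfg.diel_white_samples)
    merged = concat_samples(green, white)
    coded = assign_class_codes(candidates, ref)
    expr_cands = merged.subset([t.id for t in coded])
    accepted, low_conf, funnel = filter_lncrna(coded, scores, expr_cands, cfg.identification)
    report["stages"]["identify"] = {
        "n_candidates": len(candidates),
        "funnel": funnel.to_frame().to_dict(orient="records"),
        "n_accepted": len(accepted),
        "n_low_confidence": len(low_conf),
    }
    log.info("identify: %d candidates -> %d accepted, %d low-confidence",
             len(candidates), len(accepted), len(low_conf))
    write_tsv(funnel.to_frame(), out("funnel.tsv"))
    write_gtf(low_conf, out("low_confidence.gtf"))

    # ---- classify ------------------------------------------------------
    classified = classify_biotype(accepted)
    n_linc = sum(t.biotype == "lincRNA" for t in classified)
    n_nat = sum(t.biotype == "lncNAT" for t in classified)
    report["stages"]["classify"] = {"n_lincRNA": n_linc, "n_lncNAT": n_nat}
    write_gtf(classified, out("accepted.gtf"))

    # ---- characterize --------------------------------------------------
    coding = ref.transcripts
    summary = feature_summary(classified + coding, merged)
    write_tsv(summary.to_frame(), out("feature_summary.tsv"))
    dists = locus_distances(classified, ref)
    write_tsv(
        pd.DataFrame([{"metric": k, "median_bp": v} for k, v in dists.medians.items()]),
        out("distances.tsv"),
    )
    lnc_ids = [t.id for t in classified]
    coding_ids = [t.gene_id for t in coding]
    lnc_levels = merged.subset(lnc_ids).row_max()
    coding_levels = merged.subset(coding_ids).row_max()
    ks = None
    if len(lnc_levels) and len(coding_levels):
        stat, p = compare_expression_distributions(lnc_levels, coding_levels)
        ks = {"ks_statistic": stat, "p_value": p}
    report["stages"]["characterize"] = {
        "medians": dists.medians,
        "expression_ks_lnc_vs_coding": ks,
        "classes": {k: vars(v) for k, v in summary.classes.items()},
    }

    # ---- tissue specificity -------------------------------------------
    tissues = read_expression(cfg.tissues, cfg.tissues_samples)
    per_tissue = average_by_tissue(tissues)
    lnc_res = call_specificity(per_tissue.subset(lnc_ids), cfg.specificity)
    mrna_res = call_specificity(per_tissue.subset(coding_ids), cfg.specificity)
    write_tsv(specificity_table(lnc_res), out("specificity_lncrna.tsv"))
    write_tsv(specificity_table(mrna_res), out("specificity_mrna.tsv"))
    tau_ks = None
    if lnc_res and mrna_res:
        stat, p = specificity_distribution_compare(
            [r.tau for r in lnc_res], [r.tau for r in mrna_res]
        )
        tau_ks = {"ks_statistic": stat, "p_value": p}
    report["stages"]["tau"] = {
        "n_lncrna_scored": len(lnc_res),
        "n_lncrna_specific": sum(r.is_tissue_specific for r in lnc_res),
        "n_mrna_scored": len(mrna_res),
        "n_mrna_specific": sum(r.is_tissue_specific for r in mrna_res),
        "tau_ks_lnc_vs_mrna": tau_ks,
    }

    # ---- co-expression -------------------------------------------------
    net = build_network(merged.subset(lnc_ids), merged.subset(coding_ids), cfg.r_threshold)
    net.write_tsv(out("coexpression_edges.tsv"))
    write_tsv(degree_summary(net), out("coexpression_degrees.tsv"))
    report["stages"]["coexpress"] = {
        "n_edges": net.n_edges,
        "n_positive": net.n_positive,
        "n_negative": net.n_negative,
        "n_nodes": len(net.nodes()),
    }

    # ---- ceRNA ---------------------------------------------------------
    bindings = read_bindings(cfg.bindings)
    pairs = shared_mirna_pairs(bindings)
    write_tsv(pairs_table(pairs), out("cerna_pairs.tsv"))
    biotype_of = {t.id: t.biotype for t in classified}
    node_classes = {}
    for p in pairs:
        for t in p.key:
            node_classes[t] = biotype_of.get(t, "mRNA")
    cerna_network_export(pairs, node_classes, out("cerna_network.graphml"))
    focal_report = {}
    for focal in cfg.focal_ids:
        fpairs, competed = focal_cerna(bindings, focal)
        partners = sorted(
            p.transcript_b if p.transcript_a == focal else p.transcript_a for p in fpairs
        )
        focal_report[focal] = {
            "n_partners": len(partners),
            "partners": partners,
            "n_competed_mirnas": len(competed),
        }
    report["stages"]["cerna"] = {
        "n_pairs": len(pairs),
        "n_target_target": sum(p.pair_type == "target-target" for p in pairs),
        "n_target_mimic": sum(p.pair_type == "target-mimic" for p in pairs),
        "focal": focal_report,
    }

    # ---- diel cycling --------------------------------------------------
    keep = lnc_ids + coding_ids
    green_calls = score_matrix(green.subset(keep), cfg=cfg.cycling)
    white_calls = score_matrix(white.subset(keep), cfg=cfg.cycling)
    write_tsv(calls_table(green_calls), out("cycling_green.tsv"))
    write_tsv(calls_table(white_calls), out("cycling_white.tsv"))
    overlap = classify_overlap(green_calls, white_calls)
    write_tsv(
        pd.DataFrame(sorted(overlap.items()), columns=["transcript_id", "overlap_class"]),
        out("cycling_overlap.tsv"),
    )
    lnc_set = set(lnc_ids)
    lnc_overlap = {t: c for t, c in overlap.items() if t in lnc_set}
    counts = {c: sum(v == c for v in lnc_overlap.values())
              for c in ("both", "green-only", "white-only", "none")}
    n_cycling = len(lnc_overlap) - counts["none"]
    report["stages"]["cycling"] = {
        "n_lncrna": len(lnc_overlap),
        "n_lncrna_cycling": n_cycling,
        "fraction_lncrna_cycling": (n_cycling / len(lnc_overlap)) if lnc_overlap else None,
        "overlap_counts": counts,
    }

    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def demo(out_dir: str, seed: int = 0, sim_cfg=None) -> dict:
    """Simulate a full synthetic cohort and run the whole pipeline on it.

    Writes fixtures under ``out_dir/fixtures`` and results under
    ``out_dir/results``; returns the run report.
    """
    from .synthetic_data import SimulationConfig, simulate_all

    sim_cfg = sim_cfg or SimulationConfig(seed=seed)
    fixtures = os.path.join(out_dir, "fixtures")
    manifest = simulate_all(sim_cfg, fixtures)
    cfg = RunConfig(
        ref=os.path.join(fixtures, "ref.gtf"),
        candidates=os.path.join(fixtures, "candidates.gtf"),
        scores=os.path.join(fixtures, "scores.tsv"),
        diel_green=os.path.join(fixtures, "diel_green.tsv"),
        diel_green_samples=os.path.join(fixtures, "diel_green.samples.tsv"),
        diel_white=os.path.join(fixtures, "diel_white.tsv"),
        diel_white_samples=os.path.join(fixtures, "diel_white.samples.tsv"),
        tissues=os.path.join(fixtures, "tissues.tsv"),
        tissues_samples=os.path.join(fixtures, "tissues.samples.tsv"),
        bindings=os.path.join(fixtures, "bindings.tsv"),
        out_dir=os.path.join(out_dir, "results"),
        seed=seed,
        focal_ids=sorted(manifest["cerna"]["focal"]),
        cycling=CyclingConfig(seed=seed),
    )
    cfg.to_yaml(os.path.join(out_dir, "run_config.yaml"))
    return run_all(cfg)
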