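"""End-to-end synthetic pipeline runs with a single config and seed.

:func:`run_pipeline` chains the arms of the analysis in study order —
simulate inputs, call bait interactors, score ranked-list enrichment with
the percentile-bin decomposition, then the miRNA arm (differential
expression, dysregulated selection, co-binding prioritization) — and
returns a JSON-serializable report.  The report records every threshold
actually applied, the record counts at every filter gate (the funnel), and
truth-recovery metrics wherever the generators planted ground truth.
Identical config + seed gives a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .enrichment import bin_profile, permutation_significance
from .interactome import CallParams, call_interactors
from .mirna import (
    cobinding_counts,
    differential_mirna,
    normalize_cpm,
    prioritize_targets,
    select_dysregulated,
)
from .synthetic import (
    SimConfig,
    simulate_edges,
    simulate_ip_lfq,
    simulate_mirna_counts,
    simulate_ranked_overlap,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    run_interactome: bool = True
    run_enrichment: bool = True
    run_mirna: bool = True
    sim: SimConfig = None  # defaults to SimConfig(seed=seed)
    call_params: CallParams = None  # defaults to CallParams(seed=seed)
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    n_bins: int = 10
    mirna_alpha: float = 0.05
    pct_threshold: float = 25.0
    min_cobind: int = 8

    def resolved(self) -> "PipelineConfig":
        from dataclasses import replace

        sim = self.sim if self.sim is not None else SimConfig(seed=self.seed)
        cp = self.call_params if self.call_params is not None else CallParams(seed=self.seed)
        return replace(self, sim=sim, call_params=cp)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages in order and return the structured report."""
    cfg = cfg.resolved()
    report: dict = {
        "tool": "rbpcoreg",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "sim": asdict(cfg.sim),
            "call_params": asdict(cfg.call_params),
            "weight_exponent": cfg.weight_exponent,
            "n_permutations": cfg.n_permutations,
            "n_bins": cfg.n_bins,
            "mirna_alpha": cfg.mirna_alpha,
            "pct_threshold": cfg.pct_threshold,
            "min_cobind": cfg.min_cobind,
        },
        "stages": {},
    }
    report["parameters"]["sim"]["planted_cobind"] = [
        list(x) for x in report["parameters"]["sim"]["planted_cobind"]
    ]

    if cfg.run_interactome:
        try:
            stage = _interactome_stage(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage interactome failed: {exc}") from exc
        report["stages"]["interactome"] = stage
        logger.info(
            "interactome: %d proteins in, %d called", stage["n_proteins"], stage["n_called"]
        )

    if cfg.run_enrichment:
        try:
            stage = _enrichment_stage(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage enrichment failed: {exc}") from exc
        report["stages"]["enrichment"] = stage
        logger.info("enrichment: ES=%.3f p=%.4g", stage["es"], stage["p_nominal"] or float("nan"))

    if cfg.run_mirna:
        try:
            stage = _mirna_stage(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage mirna failed: {exc}") from exc
        report["stages"]["mirna"] = stage
        logger.info(
            "mirna: %d miRNAs in, %d selected, %d targets prioritized",
            stage["n_mirnas"], stage["n_selected"], stage["n_prioritized"],
        )

    return _round_floats(report)


def _interactome_stage(cfg: PipelineConfig) -> dict:
    m, truth = simulate_ip_lfq(cfg.sim)
    calls = call_interactors(m, cfg.call_params)
    called = {c.protein_id for c in calls if c.called}
    pass_detection = sum(
        1 for c in calls if c.n_detected_bait >= cfg.call_params.min_bait_detections
    )
    pass_fc = sum(
        1
        for c in calls
        if c.n_detected_bait >= cfg.call_params.min_bait_detections
        and c.fold_change > cfg.call_params.fc_threshold
    )
    tp = len(called & truth)
    sens = tp / len(truth) if truth else None
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return {
        "n_proteins": len(m.proteins),
        "n_pass_detection": pass_detection,
        "n_pass_detection_fc": pass_fc,
        "n_called": len(called),
        "recovery": {"n_planted": len(truth), "sensitivity": sens, "fdp": fdp},
    }


def _enrichment_stage(cfg: PipelineConfig) -> dict:
    ranked, query, truth = simulate_ranked_overlap(cfg.sim)
    res = permutation_significance(
        ranked, query, p=cfg.weight_exponent,
        n_permutations=cfg.n_permutations, seed=cfg.seed,
    )
    profile = bin_profile(ranked, query, n_bins=cfg.n_bins, p=cfg.weight_exponent)
    return {
        "n": res.n,
        "n_hits": res.n_hits,
        "es": res.es,
        "nes": res.nes,
        "p_nominal": res.p_nominal,
        "fdr_q": res.fdr_q,
        "rank_at_max_pct": res.rank_at_max_pct,
        "leading_edge_size": len(res.leading_edge),
        "bin_counts": [b.count for b in profile.bins],
        "bin1_fraction": profile.bins[0].fraction,
        "recovery": {
            "planted_top_fraction": truth["n_planted_top"] / cfg.sim.set_size,
        },
    }


def _mirna_stage(cfg: PipelineConfig) -> dict:
    counts, design, truth = simulate_mirna_counts(cfg.sim)
    cpm = normalize_cpm(counts)
    table = differential_mirna(cpm, design, alpha=cfg.mirna_alpha)
    selected = select_dysregulated(
        table, pct_threshold=cfg.pct_threshold, alpha=cfg.mirna_alpha
    )
    planted = set(truth.loc[truth["is_de"], "mirna"])
    divergent = set(table.loc[table["divergent"], "mirna"])
    sens = len(divergent & planted) / len(planted) if planted else None

    sim_edges = cfg.sim
    if not dict(sim_edges.planted_cobind):
        # default edge experiment: two planted targets straddling the threshold
        from dataclasses import replace

        high = min(cfg.min_cobind + 1, cfg.sim.n_de_mirnas)
        sim_edges = replace(
            cfg.sim,
            planted_cobind=(("T_high", high), ("T_low", min(2, high))),
        )
    edges, edge_selected, edge_truth = simulate_edges(sim_edges)
    cb = cobinding_counts(edges, edge_selected, min_cobind=cfg.min_cobind)
    prioritized = prioritize_targets(cb, cfg.min_cobind)
    return {
        "n_mirnas": len(counts.index),
        "n_divergent": len(divergent),
        "n_selected": len(selected),
        "recovery": {
            "n_planted": len(planted),
            "divergence_sensitivity": sens,
        },
        "n_edges": len(edges),
        "n_cobound_targets": len(cb),
        "n_prioritized": len(prioritized),
        "planted_prioritized": sorted(
            t for t in prioritized if t in edge_truth["planted"]
        ),
    }


def write_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, fixed float rounding)."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a JSON file; nested sim/call_params blocks optional."""
    raw = json.loads(Path(path).read_text())
    sim = SimConfig(**raw.pop("sim")) if "sim" in raw else None
    cp = CallParams(**raw.pop("call_params")) if "call_params" in raw else None
    return PipelineConfig(sim=sim, call_params=cp, **raw)
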