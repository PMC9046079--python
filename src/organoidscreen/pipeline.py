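"""End-to-end orchestration: simulate/load -> normalize -> score ->
decide -> call -> QC, with provenance.

Every stage writes its table to the output directory so stages can be
re-run individually; ``provenance.json`` records the config, seed,
package version and a SHA-256 of every artifact, and re-running with an
identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .plate_model import ScreenDataset, read_well_table, write_well_table
from .synthetic import SimulationConfig, generate_primary_screen, generate_validation_screen
from .normalization import normalize_screen
from .ssmd import DecisionParams, WeightSpec, optimal_critical_value, score_groups, summarize_groups
from .hits import HitCriteria, call_primary_hits, call_validation_hits, dedupe_by_target, select_optimal_dose
from .qc import qc_report

__all__ = ["RunConfig", "run_primary_analysis", "run_validation_analysis"]

log = logging.getLogger("organoidscreen")


@dataclass
class RunConfig:
    """Analysis parameters with the screen's published defaults.

    span 1 and degree 2 for the LOESS surface; effect bounds beta1 = 3
    and beta2 = 0.25; denominator weights 0.5/0.5; z cut 1.282 (top
    decile); FPL 0.05 for the confirmatory FPL-only rule.
    """

    out_dir: Path
    seed: int = 0
    input_path: Path | None = None
    simulation: SimulationConfig | None = None
    span: float = 1.0
    degree: int = 2
    beta1: float = 3.0
    beta2: float = 0.25
    fpl: float = 0.05
    z_cut: float = 1.282
    weights: WeightSpec = field(default_factory=WeightSpec)
    replicate_unit: str = "donor"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_provenance(out: Path, config: RunConfig, extra: dict) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    artifacts = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in (".csv", ".json")
        and p.name != "provenance.json"
    }
    payload = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "artifact_sha256": artifacts,
        **extra,
    }
    (out / "provenance.json").write_text(json.dumps(payload, indent=2, default=default))


def _load_or_simulate(config: RunConfig, validation_hits=None) -> ScreenDataset:
    if config.input_path is not None:
        log.info("stage=load path=%s", config.input_path)
        return read_well_table(config.input_path)
    sim = config.simulation or SimulationConfig(seed=config.seed)
    if validation_hits is None:
        log.info("stage=simulate kind=primary seed=%d", sim.seed)
        dataset, truth = generate_primary_screen(sim)
    else:
        log.info("stage=simulate kind=validation seed=%d", sim.seed)
        dataset, truth = generate_validation_screen(sim, validation_hits)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    truth.effects.to_csv(config.out_dir / "truth_effects.csv", index=False)
    return dataset


def _qc_to_disk(normalized, out: Path) -> None:
    report = qc_report(normalized)
    payload = {k: v.to_dict(orient="records") for k, v in report.items()}
    (out / "qc_report.json").write_text(json.dumps(payload, indent=2, default=str))
    for name, frame in report.items():
        frame.to_csv(out / f"qc_{name}.csv", index=False)
    for _, row in report["control_contrasts"].iterrows():
        if not row["available"]:
            log.warning("qc contrast unavailable: %s", row["contrast"])


def run_primary_analysis(config: RunConfig) -> Path:
    """Primary screen: LOESS + plate-median normalization, donor-replicate
    SSMD scoring, FPL/FNL-intersection critical value, dual-assay SSMD +
    z gating, optimal-dose selection and per-target deduplication."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load_or_simulate(config)
    write_well_table(dataset, out / "wells.csv")

    log.info("stage=normalize mode=plate-median span=%s degree=%d", config.span, config.degree)
    normalized = normalize_screen(dataset, span=config.span, degree=config.degree,
                                  fc_mode="plate-median")
    normalized.frame.to_csv(out / "normalized.csv", index=False)

    log.info("stage=score replicate_unit=%s", config.replicate_unit)
    groups = summarize_groups(normalized, replicate=config.replicate_unit)
    n_flagged = int((~groups["scored"]).sum())
    if n_flagged:
        log.warning("stage=score flagged_groups=%d (n < 3, not scored)", n_flagged)
    scores = score_groups(groups, weights=config.weights)
    scores.to_csv(out / "scores.csv", index=False)

    n_rep = int(scores.loc[scores["scored"], "n"].median()) if scores["scored"].any() else 3
    params = optimal_critical_value(
        DecisionParams(n=n_rep, beta1=config.beta1, beta2=config.beta2),
        mode="intersect_fpl_fnl",
    )
    (out / "decision.json").write_text(json.dumps(dataclasses.asdict(params), indent=2))
    log.info("stage=decide beta_alpha1=%.4f fpl=%.4f fnl=%.4f",
             params.beta_alpha1, params.achieved_fpl, params.achieved_fnl)

    criteria = HitCriteria(beta_alpha1=params.beta_alpha1, z_cut=config.z_cut)
    hit_table = call_primary_hits(scores, criteria)
    hit_table.to_csv(out / "hits.csv", index=False)
    optimal = select_optimal_dose(hit_table, rank="min-ssmd")
    optimal.to_csv(out / "hits_optimal_dose.csv", index=False)
    annotation = dict(
        dataset.frame.loc[dataset.frame["treatment_id"] != "",
                          ["treatment_id", "target_annotation"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    if annotation:
        deduped = dedupe_by_target(optimal, annotation)
        deduped.to_csv(out / "hits_by_target.csv", index=False)

    _qc_to_disk(normalized, out)
    _write_provenance(out, config, {"mode": "primary",
                                    "beta_alpha1": params.beta_alpha1,
                                    "n_hits": int(hit_table["is_hit"].sum()),
                                    "n_refined_hits": int(hit_table["is_refined_hit"].sum())})
    return out


def run_validation_analysis(
    config: RunConfig, primary_hits: Sequence[tuple[str, float]]
) -> Path:
    """Confirmatory screen: control-median normalization, well-replicate
    (n = 8) SSMD scoring, FPL-only critical value, SSMD-only gating, and
    mean-FC optimal-dose selection."""
    if not primary_hits:
        raise ValueError("validation analysis requires a nonempty primary hit list")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load_or_simulate(config, validation_hits=list(primary_hits))
    write_well_table(dataset, out / "wells.csv")

    log.info("stage=normalize mode=control-median")
    normalized = normalize_screen(dataset, fc_mode="control-median")
    normalized.frame.to_csv(out / "normalized.csv", index=False)

    groups = summarize_groups(normalized, replicate="well")
    scores = score_groups(groups, weights=config.weights)
    scores.to_csv(out / "scores.csv", index=False)

    n_rep = int(scores.loc[scores["scored"], "n"].median()) if scores["scored"].any() else 8
    params = optimal_critical_value(
        DecisionParams(n=n_rep, beta2=config.beta2, fpl=config.fpl), mode="fpl_only"
    )
    (out / "decision.json").write_text(json.dumps(dataclasses.asdict(params), indent=2))
    log.info("stage=decide beta_alpha1=%.4f fpl=%.4f", params.beta_alpha1, params.achieved_fpl)

    criteria = HitCriteria(beta_alpha1=params.beta_alpha1, use_z_gate=False)
    hit_table = call_validation_hits(scores, criteria)
    hit_table.to_csv(out / "hits.csv", index=False)
    optimal = select_optimal_dose(hit_table, rank="mean-fc")
    optimal.to_csv(out / "hits_optimal_dose.csv", index=False)

    _qc_to_disk(normalized, out)
    _write_provenance(out, config, {"mode": "validation",
                                    "beta_alpha1": params.beta_alpha1,
                                    "n_validated": int(hit_table["is_hit"].sum())})
    return out
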