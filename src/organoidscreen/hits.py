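"""Hit calling on scored treatment groups.

A primary hit is a treatment x dose whose UMVUE SSMD exceeds the
optimal critical value in BOTH lysozyme assays (basal and stimulated);
refined hits additionally sit in the top 10% of the fold-change
population in both assays (z > 1.282). Viability (ATP) is always
scored and reported but never gates. Gate comparisons are strict (>).

Downstream selection picks one optimal dose per treatment and one
treatment x dose per annotated target, ranked by a potency score:
min of the two lysozyme SSMDs in the primary screen, mean of the two
lysozyme mean fold changes in the confirmatory screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HitCriteria",
    "call_primary_hits",
    "call_validation_hits",
    "select_optimal_dose",
    "dedupe_by_target",
]

LYZ_ASSAYS = ("LYZ.NS", "LYZ.S")


@dataclass(frozen=True)
class HitCriteria:
    """Gates of the hit definition.

    ``beta_alpha1`` is the SSMD critical value; ``z_cut`` the top-decile
    standard-normal threshold for the refined gate; ``use_z_gate``
    distinguishes the primary rule (SSMD + z) from the confirmatory rule
    (SSMD only).
    """

    beta_alpha1: float
    z_cut: float = 1.282
    assays_required: tuple[str, ...] = LYZ_ASSAYS
    use_z_gate: bool = True
    use_viability_gate: bool = False

    def __post_init__(self) -> None:
        if not self.z_cut > 0:
            raise ValueError("z_cut must be positive")


def _wide_scores(scores: pd.DataFrame, assays: tuple[str, ...]) -> pd.DataFrame:
    """Pivot per-assay scores to one row per treatment x dose."""
    cols = [c for c in ("ssmd", "z", "mean_fc", "n") if c in scores.columns]
    wide = scores.pivot_table(
        index=["treatment_id", "dose_uM"],
        columns="assay",
        values=cols,
        aggfunc="first",
    )
    wide.columns = [f"{stat}_{assay}" for stat, assay in wide.columns]
    wide = wide.reset_index()
    for assay in assays:
        for stat in ("ssmd", "z", "mean_fc"):
            col = f"{stat}_{assay}"
            if col not in wide.columns:
                wide[col] = np.nan
    return wide


def _call(scores: pd.DataFrame, criteria: HitCriteria) -> pd.DataFrame:
    wide = _wide_scores(scores, criteria.assays_required)
    req = list(criteria.assays_required)
    ssmd_cols = [f"ssmd_{a}" for a in req]
    z_cols = [f"z_{a}" for a in req]
    complete = wide[ssmd_cols].notna().all(axis=1)
    passes_ssmd = (wide[ssmd_cols] > criteria.beta_alpha1) & complete.to_numpy()[:, None]
    wide[[f"passes_ssmd_{a}" for a in req]] = passes_ssmd.to_numpy()
    wide["incomplete"] = ~complete
    is_hit = passes_ssmd.all(axis=1) & complete
    if criteria.use_viability_gate and "ssmd_ATP" in wide.columns:
        is_hit &= wide["ssmd_ATP"].fillna(-np.inf) > -criteria.beta_alpha1
    wide["is_hit"] = is_hit
    if criteria.use_z_gate:
        passes_z = (wide[z_cols] > criteria.z_cut) & complete.to_numpy()[:, None]
        wide[[f"passes_z_{a}" for a in req]] = passes_z.to_numpy()
        wide["is_refined_hit"] = wide["is_hit"] & passes_z.all(axis=1)
    else:
        wide["is_refined_hit"] = wide["is_hit"]
    wide["potency_score"] = wide[ssmd_cols].min(axis=1)
    return wide.sort_values(["treatment_id", "dose_uM"]).reset_index(drop=True)


def call_primary_hits(scores: pd.DataFrame, criteria: HitCriteria) -> pd.DataFrame:
    """Primary-screen gating: SSMD > beta_alpha1 in both lysozyme assays
    (the hit), plus z > z_cut in both for the refined hit. Groups missing
    a required assay are flagged ``incomplete`` and never called."""
    return _call(scores, criteria)


def call_validation_hits(scores: pd.DataFrame, criteria: HitCriteria) -> pd.DataFrame:
    """Confirmatory-screen gating: SSMD-only, against the FPL-only
    critical value; no z gate."""
    if criteria.use_z_gate:
        criteria = HitCriteria(
            beta_alpha1=criteria.beta_alpha1,
            z_cut=criteria.z_cut,
            assays_required=criteria.assays_required,
            use_z_gate=False,
            use_viability_gate=criteria.use_viability_gate,
        )
    return _call(scores, criteria)


def select_optimal_dose(hit_table: pd.DataFrame, rank: str = "min-ssmd") -> pd.DataFrame:
    """One optimal dose per treatment among its hit doses.

    ``min-ssmd`` (primary) ranks by the smaller of the two lysozyme
    SSMDs; ``mean-fc`` (confirmatory) by the mean of the two lysozyme
    mean fold changes. Exact ties resolve toward the lower dose.
    """
    hits = hit_table[hit_table["is_hit"]].copy()
    if hits.empty:
        return hits.assign(rank_score=pd.Series(dtype=float))
    if rank == "min-ssmd":
        hits["rank_score"] = hits[[f"ssmd_{a}" for a in LYZ_ASSAYS]].min(axis=1)
    elif rank == "mean-fc":
        hits["rank_score"] = hits[[f"mean_fc_{a}" for a in LYZ_ASSAYS]].mean(axis=1)
    else:
        raise ValueError(f"unknown rank mode {rank!r}")
    hits = hits.sort_values(
        ["treatment_id", "rank_score", "dose_uM"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return hits.groupby("treatment_id", sort=True).head(1).reset_index(drop=True)


def dedupe_by_target(
    hit_table: pd.DataFrame, annotation: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Keep the most potent treatment x dose per annotated target.

    ``annotation`` maps treatment_id -> target; a missing annotation for
    any hit treatment is an error listing the offenders. Ties on potency
    resolve to the lexicographically first treatment id.
    """
    annotation = dict(annotation)
    hits = hit_table[hit_table["is_hit"]].copy()
    missing = sorted(set(hits["treatment_id"]) - set(annotation))
    if missing:
        raise KeyError(f"treatments without target annotation: {missing}")
    if hits.empty:
        hits["target"] = pd.Series(dtype=str)
        return hits
    hits["target"] = hits["treatment_id"].map(annotation)
    score = hits["rank_score"] if "rank_score" in hits.columns else hits["potency_score"]
    hits = hits.assign(_score=score).sort_values(
        ["target", "_score", "treatment_id", "dose_uM"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    out = hits.groupby("target", sort=True).head(1).drop(columns="_score")
    return out.reset_index(drop=True)
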