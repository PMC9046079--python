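"""Screen-level quality control.

Pure reporting over a normalized dataset: separation of the control-well
groups the stimulation scheme predicts should differ, Pearson
correlation of matched group fold changes between donor replicates, and
per plate x assay distribution shape (toxic compounds show up as a low
tail below mean - 2 SD).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .plate_model import ControlRole

__all__ = [
    "control_separation",
    "replicate_correlation",
    "distribution_summary",
    "qc_report",
]

_A = ControlRole.VEHICLE_A.value
_B = ControlRole.VEHICLE_B.value
_C = ControlRole.VEHICLE_C.value
_D = ControlRole.VEHICLE_D.value
_NC = ControlRole.NO_CELL.value

#: The reported control contrasts: (name, assay, roles_x, roles_y).
CONTROL_CONTRASTS = [
    ("vehicle_vs_no_cell_ATP", "ATP", (_A, _B, _C, _D), (_NC,)),
    ("AB_vs_CD_LYZ.NS", "LYZ.NS", (_A, _B), (_C, _D)),
    ("A_vs_B_LYZ.S", "LYZ.S", (_A,), (_B,)),
    ("no_cell_vs_AB_LYZ.NS", "LYZ.NS", (_NC,), (_A, _B)),
    ("no_cell_vs_A_LYZ.S", "LYZ.S", (_NC,), (_A,)),
]


def control_separation(
    normalized, value_column: str = "log10_value", test: str = "welch"
) -> pd.DataFrame:
    """Two-sample tests between control-well groups on log10 values.

    Welch's unequal-variance t test by default (``test="wilcoxon"`` for
    the rank-sum alternative). Contrasts whose groups have fewer than
    two wells are marked unavailable, not fatal.
    """
    frame = normalized.frame if hasattr(normalized, "frame") else normalized
    rows = []
    for name, assay, roles_x, roles_y in CONTROL_CONTRASTS:
        sub = frame[frame["assay"] == assay]
        x = sub.loc[sub["role"].isin(roles_x), value_column].dropna().to_numpy()
        y = sub.loc[sub["role"].isin(roles_y), value_column].dropna().to_numpy()
        row = {
            "contrast": name,
            "assay": assay,
            "group_x": "+".join(roles_x),
            "group_y": "+".join(roles_y),
            "n_x": len(x),
            "n_y": len(y),
            "mean_x": float(np.mean(x)) if len(x) else np.nan,
            "mean_y": float(np.mean(y)) if len(y) else np.nan,
        }
        if len(x) < 2 or len(y) < 2:
            row.update(statistic=np.nan, p=np.nan, available=False)
        else:
            if test == "welch":
                res = stats.ttest_ind(x, y, equal_var=False)
            elif test == "wilcoxon":
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
            else:
                raise ValueError(f"unknown test {test!r}")
            row.update(
                statistic=float(res.statistic), p=float(res.pvalue), available=True
            )
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_correlation(
    normalized, fc_column: str = "fold_change", min_points: int = 3
) -> pd.DataFrame:
    """Pearson r between donors on matched group mean fold changes.

    Fold changes are first collapsed to (treatment, dose, assay, donor)
    means — the quantities the screen actually scores — then correlated
    per assay for every donor pair; pairs with fewer than ``min_points``
    matched groups are flagged.
    """
    frame = normalized.frame if hasattr(normalized, "frame") else normalized
    comp = frame[frame["role"] == ControlRole.COMPOUND.value]
    per_rep = (
        comp.groupby(["assay", "treatment_id", "dose_uM", "donor"])[fc_column]
        .mean()
        .reset_index()
    )
    rows = []
    for assay, sub in per_rep.groupby("assay"):
        wide = sub.pivot_table(
            index=["treatment_id", "dose_uM"], columns="donor", values=fc_column
        )
        for d1, d2 in combinations(sorted(wide.columns), 2):
            paired = wide[[d1, d2]].dropna()
            row = {"assay": assay, "donor_1": d1, "donor_2": d2, "n_matched": len(paired)}
            if len(paired) < min_points:
                row.update(pearson_r=np.nan, available=False)
            else:
                r = stats.pearsonr(paired[d1], paired[d2]).statistic
                row.update(pearson_r=float(r), available=True)
            rows.append(row)
    return pd.DataFrame(rows)


def distribution_summary(
    normalized, value_column: str = "fold_change", min_wells: int = 10
) -> pd.DataFrame:
    """Per plate x assay: mean, SD, sample skewness, and the fraction of
    wells below mean - 2 SD (the toxic low tail). Constant plates are
    flagged (skewness undefined)."""
    frame = normalized.frame if hasattr(normalized, "frame") else normalized
    rows = []
    for (plate, assay), sub in frame.groupby(["plate", "assay"]):
        x = sub[value_column].dropna().to_numpy()
        row = {"plate": plate, "assay": assay, "n_wells": len(x)}
        if len(x) < min_wells:
            row.update(mean=np.nan, sd=np.nan, skewness=np.nan,
                       frac_below_2sd=np.nan, available=False)
        else:
            mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if sd == 0:
                row.update(mean=mean, sd=0.0, skewness=np.nan,
                           frac_below_2sd=0.0, available=False)
            else:
                row.update(
                    mean=mean,
                    sd=sd,
                    skewness=float(stats.skew(x, bias=False)),
                    frac_below_2sd=float(np.mean(x < mean - 2 * sd)),
                    available=True,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def qc_report(normalized) -> dict[str, pd.DataFrame]:
    """All three QC tables in one dict (pure; never mutates the input)."""
    return {
        "control_contrasts": control_separation(normalized),
        "replicate_correlations": replicate_correlation(normalized),
        "distribution_summaries": distribution_summary(normalized),
    }
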