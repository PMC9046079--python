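"""Compositional statistics for cell-type count tables.

Enrichment or depletion of a cell type under treatment is measured per
stratum (timepoint or cluster) by the odds ratio of the 2x2 table
(type vs rest) x (treated vs control), with a Fisher exact p-value, a
Woolf log-normal 95% confidence interval, and Benjamini-Hochberg FDR
adjustment across all tested pairs. Types too rare to test — below 0.5%
of cells or below 10 cells in either condition, depending on mode — are
reported untested with a reason rather than dropped.

Also provides Cohen's d with the screen's magnitude bins, 0-1 min-max
score scaling, and the crypt-count exceedance statistic (fraction of
test counts strictly above the reference cohort's 90th-percentile
count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "EffectSizeResult",
    "abundance_filter",
    "fisher_enrichment",
    "enrichment_timecourse",
    "fdr_adjust",
    "cohens_d",
    "minmax_scale",
    "exceedance_fraction",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Odds-ratio enrichment of one cell type in one stratum."""

    cell_type: str
    stratum: object
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    tested: bool = True
    filter_reason: str = ""


#: Magnitude bins for |d|, with the conventional dollar-sign shorthand.
_D_BINS = [
    (0.5, "negligible", ""),
    (0.8, "small", "$"),
    (1.2, "medium", "$$"),
    (2.0, "large", "$$$"),
    (np.inf, "very large", "$$$$"),
]


@dataclass(frozen=True)
class EffectSizeResult:
    """Cohen's d between two samples, with magnitude bin."""

    label: str
    cohens_d: float
    magnitude_bin: str
    magnitude_symbol: str


def abundance_filter(
    table: pd.DataFrame,
    mode: str = "fraction",
    min_fraction: float = 0.005,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Eligibility of each (cell_type, stratum) for enrichment testing.

    ``fraction`` mode requires the type to account for at least
    ``min_fraction`` of cells in BOTH conditions of the stratum
    (inclusive); ``count`` mode requires at least ``min_cells`` cells in
    both. Returns a frame with ``eligible`` and ``filter_reason``.
    """
    if mode not in ("fraction", "count"):
        raise ValueError(f"unknown abundance filter mode {mode!r}")
    totals = table.groupby(["condition", "stratum"])["n_cells"].sum()
    rows = []
    for (ct, st), sub in table.groupby(["cell_type", "stratum"]):
        counts = sub.groupby("condition")["n_cells"].sum()
        reasons = []
        for cond in ("control", "treated"):
            n = int(counts.get(cond, 0))
            total = int(totals.get((cond, st), 0))
            if mode == "fraction":
                frac = n / total if total else 0.0
                if frac < min_fraction:
                    reasons.append(
                        f"{cond}: {frac:.4f} of cells < {min_fraction}"
                    )
            else:
                if n < min_cells:
                    reasons.append(f"{cond}: {n} cells < {min_cells}")
        rows.append(
            {
                "cell_type": ct,
                "stratum": st,
                "eligible": not reasons,
                "filter_reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Fisher exact test of one 2x2 table.

    Layout: ``a`` = type cells treated, ``b`` = rest treated, ``c`` =
    type control, ``d`` = rest control. The two-sided p sums all
    hypergeometric outcomes no more probable than the observed one (the
    method of small p-values). The odds ratio is the cross-product
    (a*d)/(b*c); if any cell is zero, 0.5 is added to every cell
    (Haldane-Anscombe) for the OR and its Woolf 95% CI
    exp(log OR +/- 1.96 * sqrt(sum of reciprocal cells)).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return EnrichmentResult(
            "", None, np.nan, np.nan, np.nan, np.nan,
            tested=False, filter_reason="empty margin",
        )
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(or_) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_) + 1.96 * se))
    return EnrichmentResult("", None, float(or_), ci_low, ci_high, p)


def enrichment_timecourse(
    table: pd.DataFrame,
    mode: str = "fraction",
    min_fraction: float = 0.005,
    min_cells: int = 10,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Odds-ratio enrichment of every eligible (cell type, stratum).

    Expects columns condition ∈ {control, treated}, stratum, cell_type,
    n_cells (summing replicate samples if present). FDR adjustment runs
    over all tested pairs in the call; ineligible pairs appear with
    ``tested = False`` and their filter reason.
    """
    agg = (
        table.groupby(["condition", "stratum", "cell_type"])["n_cells"]
        .sum()
        .reset_index()
    )
    elig = abundance_filter(agg, mode=mode, min_fraction=min_fraction, min_cells=min_cells)
    totals = agg.groupby(["condition", "stratum"])["n_cells"].sum()
    rows = []
    for rec in elig.itertuples(index=False):
        ct, st = rec.cell_type, rec.stratum
        sub = agg[(agg["cell_type"] == ct) & (agg["stratum"] == st)]
        counts = sub.set_index("condition")["n_cells"]
        a = int(counts.get("treated", 0))
        c = int(counts.get("control", 0))
        b = int(totals.get(("treated", st), 0)) - a
        d = int(totals.get(("control", st), 0)) - c
        row = {
            "cell_type": ct, "stratum": st,
            "n_treated": a, "n_control": c,
            "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p": np.nan, "q": np.nan,
            "tested": False, "filter_reason": rec.filter_reason,
        }
        if rec.eligible:
            res = fisher_enrichment(a, b, c, d)
            if res.tested:
                row.update(
                    odds_ratio=res.odds_ratio, ci_low=res.ci_low,
                    ci_high=res.ci_high, p=res.p, tested=True, filter_reason="",
                )
            else:
                row["filter_reason"] = res.filter_reason
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = fdr_adjust(out.loc[tested, "p"].to_numpy(), fdr_method)
    return out


def fdr_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment; output order matches input.

    ``bh`` is the Benjamini-Hochberg step-up FDR; ``bonferroni`` the
    family-wise bound, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method=key)[1]


def cohens_d(x: np.ndarray, y: np.ndarray, label: str = "") -> EffectSizeResult:
    """Cohen's d = (mean(x) - mean(y)) / pooled SD, with magnitude bin.

    Pooled SD weights the group variances by n-1. Zero pooled SD is
    undefined and raises; callers screening many contrasts should catch
    and flag. Bin thresholds on |d|: 0.5, 0.8, 1.2, 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    d = float((x.mean() - y.mean()) / np.sqrt(pooled_var))
    for upper, name, symbol in _D_BINS:
        if abs(d) < upper or upper == np.inf:
            return EffectSizeResult(label, d, name, symbol)
    raise AssertionError("unreachable")


def minmax_scale(scores: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] as (s - min) / (max - min); constant input errors."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = np.nanmin(scores), np.nanmax(scores)
    if hi == lo:
        raise ValueError("constant input: min-max scaling undefined")
    return (scores - lo) / (hi - lo)


def exceedance_fraction(
    reference_counts: np.ndarray,
    test_counts: np.ndarray,
    percentile: float = 90.0,
) -> tuple[float, float]:
    """Fraction of test counts strictly above a reference percentile.

    The cutoff is the empirical (inverse-ECDF) percentile of the
    reference: the smallest observed value with at least ``percentile``%
    of the reference at or below it — always an attained (integer)
    count. Returns (cutoff, fraction of test strictly greater).
    """
    ref = np.sort(np.asarray(reference_counts))
    test = np.asarray(test_counts)
    if len(ref) == 0 or len(test) == 0:
        raise ValueError("reference and test counts must be nonempty")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    # smallest index with ECDF >= percentile/100
    idx = int(np.ceil(percentile / 100.0 * len(ref))) - 1
    cutoff = float(ref[max(idx, 0)])
    return cutoff, float(np.mean(test > cutoff))
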