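"""Replicate SSMD scoring and noncentral-t decision thresholds.

The strictly standardized mean difference (SSMD) of a treatment group is
the mean of its per-replicate fold changes divided by their standard
deviation. With n replicates, the robust uniformly minimum-variance
unbiased estimate (UMVUE) is

    SSMD = c_n * d_bar / sqrt(w_i * s_i^2 + w_0 * s_0^2),
    c_n  = Gamma((n-1)/2) / Gamma((n-2)/2) * sqrt(2/(n-1)),

where d_bar and s_i^2 are the group sample mean and variance, s_0^2 is
the median of all group variances (a stabilizing shrinkage target), and
w_i = w_0 = 0.5 by default. With w_i = 1 the estimator is exactly
unbiased for the true standardized effect.

Hit thresholds come from error-rate curves of the noncentral t
distribution. For a critical value beta_a1 on the UMVUE scale, the
false-positive level against a bounding weak effect beta2 and the
false-negative level against a bounding strong effect beta1 are

    FPL = 1 - F_t(n-1, sqrt(n)*beta2)( beta_a1 / (c_n * k) ),
    FNL =     F_t(n-1, sqrt(n)*beta1)( beta_a1 / (c_n * k) ),

with k = sqrt(1/n). The optimal critical value either balances the two
(FPL = FNL intersection) or meets a target FPL alone. Dividing by
c_n * k maps the UMVUE-scale threshold onto the t statistic
sqrt(n) * d_bar / s whose distribution is noncentral t; the raw-scale
variant (divide by k only) is available via ``scale="raw"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "GroupSummary",
    "VariancePool",
    "WeightSpec",
    "DecisionParams",
    "umvue_factor",
    "summarize_groups",
    "pool_variance",
    "replicate_ssmd",
    "score_groups",
    "fold_change_zscores",
    "noncentral_t_cdf",
    "fpl_curve",
    "fnl_curve",
    "optimal_critical_value",
    "simulate_ssmd_groups",
]


def umvue_factor(n: int | np.ndarray) -> float | np.ndarray:
    """The UMVUE correction c_n = Gamma((n-1)/2)/Gamma((n-2)/2) * sqrt(2/(n-1)).

    Defined for n >= 3 (Gamma has a pole at 0, so c_2 degenerates).
    Computed via log-gamma for numerical stability at large n.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise ValueError("UMVUE factor requires n >= 3")
    out = np.exp(gammaln((n - 1) / 2) - gammaln((n - 2) / 2)) * np.sqrt(2 / (n - 1))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WeightSpec:
    """Weights of the group vs pooled variance in the SSMD denominator."""

    w_i: float = 0.5
    w_0: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.w_i + self.w_0 - 1.0) > 1e-12:
            raise ValueError("weights must satisfy w_i + w_0 = 1")


@dataclass(frozen=True)
class GroupSummary:
    """Replicate fold changes of one treatment x dose x assay group."""

    treatment_id: str
    dose_uM: float
    assay: str
    n: int
    d_bar: float
    s2: float


@dataclass(frozen=True)
class VariancePool:
    """Median of group variances within one assay (the s_0^2 shrinkage)."""

    assay: str
    s0_sq: float
    n_groups_pooled: int


@dataclass
class DecisionParams:
    """Design of an SSMD decision rule and its solved critical value.

    beta1 bounds the effects a miss would forfeit (FNL side, default 3,
    'at least strong'); beta2 bounds the effects a false flag would
    claim (FPL side, default 0.25, 'at least very weak'). k = sqrt(1/n)
    and c_n are derived, never stored free.
    """

    n: int
    beta1: float = 3.0
    beta2: float = 0.25
    fpl: float | None = None
    fnl: float | None = None
    scale: str = "umvue"  # "umvue" or "raw"
    beta_alpha1: float | None = None
    achieved_fpl: float | None = None
    achieved_fnl: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("decision design requires n >= 3 (c_n undefined below)")
        if self.scale not in ("umvue", "raw"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def k(self) -> float:
        return math.sqrt(1.0 / self.n)

    @property
    def c_n(self) -> float:
        return umvue_factor(self.n)

    def _t_stat(self, beta_alpha1: float) -> float:
        denom = self.c_n * self.k if self.scale == "umvue" else self.k
        return beta_alpha1 / denom


def summarize_groups(
    normalized,
    replicate: str = "donor",
    fc_column: str = "fold_change",
) -> pd.DataFrame:
    """Collapse normalized wells to per-group replicate summaries.

    Groups are treatment x dose x assay; the replicate unit defaults to
    the donor (one fold change per donor, averaging if a donor
    contributes several wells) and can be set to ``"well"`` for designs
    where wells are the replicates (confirmatory screen, n = 8).

    Returns one row per group with n, d_bar, s2 and a ``scored`` flag;
    groups with n < 3 are flagged, never dropped.
    """
    frame = normalized.frame if hasattr(normalized, "frame") else normalized
    comp = frame[frame["role"] == "COMPOUND"].copy()
    if comp.empty:
        return pd.DataFrame(
            columns=["treatment_id", "dose_uM", "assay", "n", "d_bar", "s2", "scored"]
        )
    if replicate == "donor":
        per_rep = (
            comp.groupby(["treatment_id", "dose_uM", "assay", "donor"], sort=True)[
                fc_column
            ]
            .mean()
            .reset_index()
        )
    elif replicate == "well":
        per_rep = comp[["treatment_id", "dose_uM", "assay", fc_column]].copy()
    else:
        raise ValueError(f"unknown replicate unit {replicate!r}")
    grouped = per_rep.groupby(["treatment_id", "dose_uM", "assay"], sort=True)[fc_column]
    out = grouped.agg(n="count", d_bar="mean", s2="var").reset_index()
    out["s2"] = out["s2"].fillna(0.0)
    out["scored"] = out["n"] >= 3
    return out


def pool_variance(groups: pd.DataFrame, assay: str | None = None) -> VariancePool:
    """s_0^2 = median of group variances (per assay across the screen)."""
    sub = groups if assay is None else groups[groups["assay"] == assay]
    sub = sub[sub["scored"]] if "scored" in sub.columns else sub
    if sub.empty:
        raise ValueError(f"no scorable groups to pool for assay {assay!r}")
    return VariancePool(
        assay=assay if assay is not None else "all",
        s0_sq=float(np.median(sub["s2"].to_numpy())),
        n_groups_pooled=int(len(sub)),
    )


def replicate_ssmd(
    d_bar: float | np.ndarray,
    s2: float | np.ndarray,
    n: int | np.ndarray,
    s0_sq: float,
    weights: WeightSpec = WeightSpec(),
) -> float | np.ndarray:
    """UMVUE SSMD of one or many groups.

    Vectorized over ``d_bar``/``s2``/``n``. Returns NaN where the
    denominator is zero (flagged, never an exception, so screens with a
    few degenerate groups still score).
    """
    d_bar = np.asarray(d_bar, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    denom_sq = weights.w_i * s2 + weights.w_0 * s0_sq
    c = umvue_factor(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom_sq > 0, c * d_bar / np.sqrt(denom_sq), np.nan)
    return float(out) if out.ndim == 0 else out


def fold_change_zscores(mean_fcs: np.ndarray) -> np.ndarray:
    """z = meanFC / SD_pop within one assay's population of group means.

    SD_pop is the sample (n-1) standard deviation of all group mean fold
    changes in scope. Returns NaN if fewer than two groups or zero SD.
    """
    mean_fcs = np.asarray(mean_fcs, dtype=float)
    valid = mean_fcs[~np.isnan(mean_fcs)]
    if len(valid) < 2:
        return np.full_like(mean_fcs, np.nan)
    sd = float(np.std(valid, ddof=1))
    if sd == 0:
        return np.full_like(mean_fcs, np.nan)
    return mean_fcs / sd


def score_groups(
    groups: pd.DataFrame, weights: WeightSpec = WeightSpec()
) -> pd.DataFrame:
    """Attach s0^2, UMVUE SSMD, mean FC and z-score to group summaries.

    Pooling and the z-score population are per assay across the whole
    screen. Groups flagged unscorable keep NaN statistics.
    """
    out = groups.copy()
    out["s0_sq"] = np.nan
    out["ssmd"] = np.nan
    out["mean_fc"] = out["d_bar"]
    out["z"] = np.nan
    for assay in out["assay"].unique():
        sel = (out["assay"] == assay) & out["scored"]
        if not sel.any():
            continue
        pool = pool_variance(out[out["assay"] == assay], assay=assay)
        out.loc[sel, "s0_sq"] = pool.s0_sq
        out.loc[sel, "ssmd"] = replicate_ssmd(
            out.loc[sel, "d_bar"].to_numpy(),
            out.loc[sel, "s2"].to_numpy(),
            out.loc[sel, "n"].to_numpy(),
            pool.s0_sq,
            weights,
        )
        out.loc[sel, "z"] = fold_change_zscores(out.loc[sel, "mean_fc"].to_numpy())
    return out


def noncentral_t_cdf(x: float | np.ndarray, df: int, ncp: float) -> float | np.ndarray:
    """P(T <= x) for T ~ noncentral t(df, ncp)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    out = stats.nct.cdf(x, df, ncp)
    return float(out) if np.ndim(out) == 0 else out


def fpl_curve(beta_alpha1: float, params: DecisionParams) -> float:
    """False-positive level of threshold beta_alpha1 against effect beta2."""
    t = params._t_stat(beta_alpha1)
    return 1.0 - float(
        noncentral_t_cdf(t, params.n - 1, math.sqrt(params.n) * params.beta2)
    )


def fnl_curve(beta_alpha1: float, params: DecisionParams) -> float:
    """False-negative level of threshold beta_alpha1 against effect beta1."""
    t = params._t_stat(beta_alpha1)
    return float(noncentral_t_cdf(t, params.n - 1, math.sqrt(params.n) * params.beta1))


def _bisect(f, lo: float, hi: float, tol: float = 1e-6, max_iter: int = 200) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise ValueError(
            f"no sign change on bracket [{lo}, {hi}]: f(lo)={flo:.6g}, f(hi)={fhi:.6g}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if fmid == 0 or (hi - lo) / 2 < tol:
            return mid
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi, fhi = mid, fmid
    return 0.5 * (lo + hi)


def optimal_critical_value(
    params: DecisionParams,
    mode: str = "intersect_fpl_fnl",
    bracket: tuple[float, float] = (1e-9, 20.0),
    tol: float = 1e-6,
) -> DecisionParams:
    """Solve for the optimal SSMD critical value beta_alpha1.

    ``intersect_fpl_fnl`` balances the two error curves (their unique
    crossing, since FPL strictly decreases and FNL strictly increases in
    the threshold); requires beta1 > beta2. ``fpl_only`` meets
    ``params.fpl`` exactly, ignoring FNL (the stricter confirmatory-
    screen rule). Returns a copy of ``params`` with ``beta_alpha1`` and
    both achieved error levels filled in.
    """
    if mode == "intersect_fpl_fnl":
        if not params.beta1 > params.beta2:
            raise ValueError("intersection mode requires beta1 > beta2")
        f = lambda b: fnl_curve(b, params) - fpl_curve(b, params)
    elif mode == "fpl_only":
        if params.fpl is None or not 0 < params.fpl < 1:
            raise ValueError("fpl_only mode requires a target FPL in (0, 1)")
        f = lambda b: fpl_curve(b, params) - params.fpl
    else:
        raise ValueError(f"unknown mode {mode!r}")
    root = _bisect(f, *bracket, tol=tol)
    return replace(
        params,
        beta_alpha1=root,
        achieved_fpl=fpl_curve(root, params),
        achieved_fnl=fnl_curve(root, params),
    )


def simulate_ssmd_groups(
    rng: np.random.Generator,
    n_groups: int,
    n: int,
    beta: float,
    sigma: float = 1.0,
    weights: WeightSpec = WeightSpec(w_i=1.0, w_0=0.0),
    s0_sq: float | None = None,
) -> np.ndarray:
    """Draw replicate groups at a true standardized effect and score them.

    Each group is ``n`` values from Normal(beta * sigma, sigma); the
    returned UMVUE SSMDs use unit group weights by default (the exactly
    unbiased form the error-rate theory describes). Pass ``weights`` and
    ``s0_sq`` (default: median of the simulated group variances) to
    study the pooled pipeline estimator instead.
    """
    x = rng.normal(beta * sigma, sigma, size=(n_groups, n))
    d_bar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    pool = float(np.median(s2)) if s0_sq is None else s0_sq
    return replicate_ssmd(d_bar, s2, np.full(n_groups, n), pool, weights)
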