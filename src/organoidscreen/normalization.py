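"""Plate normalization: log transform, LOESS spatial correction, and
fold changes.

Raw well signals are log10-transformed, a local-regression (LOESS)
surface over (row, column) is fitted per plate and assay to capture
systematic row/column/edge artifacts, and each well is corrected by
subtracting the median-centred surface:

    corrected_ij = x_ij - (fit_ij - median(fit))

Fold changes are then differences on the log10 scale: against the plate
median for the primary screen, or against the median of per-assay
vehicle control wells for the confirmatory screen. All fold changes stay
in log10 units; use ``10**fc`` for linear-scale ratios in reports.

The LOESS dialect is a 2-predictor local polynomial regression on the
integer (row, col) coordinates with a tricube distance kernel, span
expressed as the fraction of points entering each local fit, polynomial
degree 2 by default, and no robustness iterations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .plate_model import AssayKind, ControlRole, PlateGrid, ScreenDataset, pivot_to_grid

__all__ = [
    "log10_transform",
    "loess_surface",
    "loess_surface_correct",
    "plate_fold_change",
    "control_fold_change",
    "normalize_screen",
    "CONTROL_ROLES_BY_ASSAY",
]

#: Vehicle roles eligible as Eq.-style controls per assay: ATP uses all
#: vehicle wells; LYZ.NS uses wells basal in the NS phase (A, B); LYZ.S
#: uses wells basal in NS then stimulated in S (A only).
CONTROL_ROLES_BY_ASSAY: dict[str, frozenset[str]] = {
    "ATP": frozenset(
        {r.value for r in (ControlRole.VEHICLE_A, ControlRole.VEHICLE_B,
                           ControlRole.VEHICLE_C, ControlRole.VEHICLE_D)}
    ),
    "LYZ.NS": frozenset({ControlRole.VEHICLE_A.value, ControlRole.VEHICLE_B.value}),
    "LYZ.S": frozenset({ControlRole.VEHICLE_A.value}),
}


def log10_transform(dataset: ScreenDataset) -> ScreenDataset:
    """Add a ``log10_value`` column (raw values validated positive)."""
    frame = dataset.frame.copy()
    frame["log10_value"] = np.log10(frame["raw_value"].to_numpy())
    out = ScreenDataset.__new__(ScreenDataset)
    out.frame = frame
    out.geometry = dataset.geometry
    out.provenance = dict(dataset.provenance)
    return out


def _poly_basis(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(u)]
    if degree >= 1:
        cols += [u, v]
    if degree >= 2:
        cols += [u * v, u**2, v**2]
    return np.column_stack(cols)


def loess_surface(
    points: np.ndarray,
    values: np.ndarray,
    eval_points: np.ndarray,
    span: float = 1.0,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression surface over 2D coordinates.

    ``points``: (n, 2) fit coordinates; ``values``: (n,) responses;
    ``eval_points``: (m, 2) where to evaluate. For each evaluation point
    the nearest ``ceil(span * n)`` fit points get tricube weights
    ``(1 - (d/d_max)^3)^3`` and a degree-``degree`` polynomial is fitted
    by weighted least squares.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    eval_points = np.asarray(eval_points, dtype=float)
    n = len(points)
    n_params = _poly_basis(points[:1, 0], points[:1, 1], degree).shape[1]
    if n < n_params:
        raise ValueError(
            f"need at least {n_params} points for degree-{degree} local fit, got {n}"
        )
    q = max(int(np.ceil(span * n)), n_params)
    q = min(q, n)

    # all pairwise distances eval x fit
    d = np.sqrt(
        ((eval_points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    )
    # bandwidth per eval point = distance to q-th nearest fit point
    dmax = np.partition(d, q - 1, axis=1)[:, q - 1]
    dmax = np.maximum(dmax, 1e-12)
    w = np.clip(1.0 - (d / dmax[:, None]) ** 3, 0.0, None) ** 3

    X = _poly_basis(points[:, 0], points[:, 1], degree)  # (n, p)
    B = _poly_basis(eval_points[:, 0], eval_points[:, 1], degree)  # (m, p)
    # batched WLS: per eval point solve (X' W X) beta = X' W y
    A = np.einsum("mn,np,nq->mpq", w, X, X)
    b = np.einsum("mn,np,n->mp", w, X, values)
    try:
        coef = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coef = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in zip(A, b)])
    return np.einsum("mp,mp->m", B, coef)


def loess_surface_correct(
    grid: PlateGrid, span: float = 1.0, degree: int = 2
) -> tuple[PlateGrid, PlateGrid]:
    """LOESS spatial correction of one plate x assay grid.

    Non-missing cells define the surface; every cell of the plate
    (including masked ones) receives a surface value by evaluation, but
    masked cells never influence the fit. The correction subtracts the
    surface re-centred at its median over the fitted cells, so a
    constant plate is returned unchanged and adding a constant shifts
    the output by exactly that constant.

    Returns ``(corrected, fit)`` grids.
    """
    values = grid.values
    n_rows, n_cols = values.shape
    rr, cc = np.meshgrid(
        np.arange(1, n_rows + 1), np.arange(1, n_cols + 1), indexing="ij"
    )
    observed = ~np.isnan(values)
    n_params = 6 if degree >= 2 else (3 if degree == 1 else 1)
    if observed.sum() < n_params:
        raise ValueError(
            f"plate {grid.plate_id} [{grid.assay}]: only {int(observed.sum())} "
            f"wells available, need >= {n_params} for the degree-{degree} surface"
        )
    pts = np.column_stack([rr[observed], cc[observed]])
    all_pts = np.column_stack([rr.ravel(), cc.ravel()])
    fit_flat = loess_surface(pts, values[observed], all_pts, span=span, degree=degree)
    fit = fit_flat.reshape(n_rows, n_cols)
    center = np.median(fit[observed])
    corrected = values - (fit - center)
    return (
        PlateGrid(grid.plate_id, grid.assay, corrected),
        PlateGrid(grid.plate_id, grid.assay, fit),
    )


def plate_fold_change(
    values: np.ndarray, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Fold change vs the plate median on corrected log10 values.

    ``exclude`` marks wells (e.g. no-cell) left out of the median; they
    still receive fold changes. The median of the returned values over
    included wells is 0 by construction.
    """
    values = np.asarray(values, dtype=float)
    if exclude is None:
        exclude = np.zeros(values.shape, dtype=bool)
    included = ~exclude & ~np.isnan(values)
    if not included.any():
        raise ValueError("all wells excluded from the plate median")
    return values - np.median(values[included])


def control_fold_change(
    dataset: ScreenDataset,
    assay: AssayKind | str,
    value_column: str = "log10_value",
) -> pd.Series:
    """Fold change vs the median of eligible vehicle wells, per plate.

    Control selection follows the stimulation scheme: ATP uses all
    vehicle wells; LYZ.NS uses roles A and B (basal in the NS phase);
    LYZ.S uses role A only (non-stimulated in NS, then stimulated in S).
    Indexed like ``dataset.frame`` rows for the given assay.
    """
    assay = AssayKind(assay).value
    roles = CONTROL_ROLES_BY_ASSAY[assay]
    frame = dataset.frame
    sub = frame[frame["assay"] == assay]
    out = pd.Series(np.nan, index=sub.index, name="fold_change")
    for plate, plate_rows in sub.groupby("plate"):
        ctrl = plate_rows[plate_rows["role"].isin(roles)]
        if ctrl.empty:
            raise ValueError(
                f"no eligible control wells (roles {sorted(roles)}) on plate "
                f"{plate} for assay {assay}"
            )
        med = float(ctrl[value_column].median())
        out.loc[plate_rows.index] = plate_rows[value_column] - med
    return out


def normalize_screen(
    dataset: ScreenDataset,
    span: float = 1.0,
    degree: int = 2,
    fc_mode: str = "plate-median",
    fit_mask_roles: tuple[str, ...] = (ControlRole.NO_CELL.value,),
    median_exclude_roles: tuple[str, ...] = (ControlRole.NO_CELL.value,),
) -> ScreenDataset:
    """Full normalization of a screen dataset.

    ``plate-median`` mode (primary screen): log10 transform, per
    plate x assay LOESS correction (no-cell wells excluded from the fit
    and the median but still corrected), then fold change against the
    plate median. ``control-median`` mode (confirmatory screen): log10
    transform, then fold change against the per-assay vehicle-control
    median, without spatial correction.

    Adds columns ``log10_value``, ``loess_fit``, ``corrected``,
    ``fold_change`` (the first two are NaN in control-median mode).
    """
    if fc_mode not in ("plate-median", "control-median"):
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    ds = log10_transform(dataset)
    frame = ds.frame
    frame["loess_fit"] = np.nan
    frame["corrected"] = np.nan
    frame["fold_change"] = np.nan

    if fc_mode == "control-median":
        for assay in ds.assays:
            fc = control_fold_change(ds, assay, value_column="log10_value")
            frame.loc[fc.index, "fold_change"] = fc
            frame.loc[fc.index, "corrected"] = frame.loc[fc.index, "log10_value"]
        ds.provenance["normalization"] = {"fc_mode": fc_mode}
        return ds

    for plate in ds.plates:
        for assay in ds.assays:
            grid = pivot_to_grid(
                ds, plate, assay, mask_roles=fit_mask_roles, column="log10_value"
            )
            corrected, fit = loess_surface_correct(grid, span=span, degree=degree)
            sel = (frame["plate"] == plate) & (frame["assay"] == assay)
            rows = frame.loc[sel, "well_row"].to_numpy() - 1
            cols = frame.loc[sel, "well_col"].to_numpy() - 1
            fit_vals = fit.values[rows, cols]
            frame.loc[sel, "loess_fit"] = fit_vals
            # masked wells get corrected values too (surface evaluated there)
            observed = ~np.isnan(grid.values)
            center = np.median(fit.values[observed])
            frame.loc[sel, "corrected"] = (
                frame.loc[sel, "log10_value"].to_numpy() - (fit_vals - center)
            )
            exclude = frame.loc[sel, "role"].isin(median_exclude_roles).to_numpy()
            frame.loc[sel, "fold_change"] = plate_fold_change(
                frame.loc[sel, "corrected"].to_numpy(), exclude=exclude
            )
    ds.provenance["normalization"] = {
        "fc_mode": fc_mode,
        "span": span,
        "degree": degree,
        "fit_mask_roles": list(fit_mask_roles),
        "median_exclude_roles": list(median_exclude_roles),
    }
    return ds
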