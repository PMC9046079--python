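"""Synthetic screens and composition tables with known ground truth.

The generator emulates the statistical structure of a multiplexed
384-well organoid screen: log10-scale well signals with smooth row/column
spatial artifacts and plate offsets, four-dose treatment effects with a
Hill dose-response, correlated basal/stimulated lysozyme responses for
abundance-type hits, ATP toxicity above a dose threshold, vehicle wells
in four stimulation-order roles, no-cell background wells, and three
donor replicates. Every draw comes from a single seeded generator in a
fixed documented order, so identical configs produce identical tables.

True effects are expressed on the SSMD scale: a hit simulated at true
SSMD ``beta`` shifts its wells by ``beta * noise_sd`` log10 units at full
dose, so the scoring stage's effect estimates can be compared directly
against the decision theory's effect bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_model import (
    AssayKind,
    ControlRole,
    ScreenDataset,
    VEHICLE_ROLES,
    WELL_TABLE_COLUMNS,
)

__all__ = [
    "HitSpec",
    "ToxicitySpec",
    "SimulationConfig",
    "TruthTable",
    "generate_primary_screen",
    "generate_validation_screen",
    "generate_composition_counts",
    "default_hit_spec",
    "default_toxicity_spec",
]

_ASSAYS = [a.value for a in AssayKind]

#: Which roles are stimulated in each lysozyme phase. A-D label the
#: stimulation order: A = basal then stimulated (the compound-well
#: protocol), B = never stimulated, C = stimulated twice, D = stimulated
#: then basal.
STIMULATED_IN_NS = {ControlRole.VEHICLE_C.value, ControlRole.VEHICLE_D.value}
STIMULATED_IN_S = {
    ControlRole.VEHICLE_A.value,
    ControlRole.VEHICLE_C.value,
    ControlRole.COMPOUND.value,
}


@dataclass(frozen=True)
class HitSpec:
    """A designed treatment effect.

    ``assay`` is one of ``ATP``, ``LYZ.NS``, ``LYZ.S`` or ``LYZ.BOTH``;
    ``LYZ.BOTH`` applies one shared latent effect to both lysozyme
    readouts (an abundance-type hit, correlation 1), while ``LYZ.S``
    alone models a secretion-only hit. ``beta`` is the true SSMD at
    saturating dose; the dose-response is a Hill curve with midpoint
    ``ec50_uM`` and slope ``hill``.
    """

    treatment_id: str
    assay: str
    beta: float
    ec50_uM: float = 0.4
    hill: float = 2.0

    def response(self, dose: np.ndarray | float) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return dose**self.hill / (dose**self.hill + self.ec50_uM**self.hill)


@dataclass(frozen=True)
class ToxicitySpec:
    """ATP drop (log10 units) applied at and above a dose threshold."""

    treatment_id: str
    dose_threshold_uM: float
    atp_drop_log10: float


def default_hit_spec() -> list[HitSpec]:
    """Spiked truth for the default primary screen: ten abundance hits
    (shared LYZ.NS/LYZ.S effect) and five secretion-only hits, all at
    true SSMD 3 ('at least strong effect' on the decision theory's
    scale)."""
    hits = [HitSpec(f"C{i:04d}", "LYZ.BOTH", 3.0) for i in range(1, 11)]
    hits += [HitSpec(f"C{i:04d}", "LYZ.S", 3.0) for i in range(11, 16)]
    return hits


def default_toxicity_spec() -> list[ToxicitySpec]:
    """Five compounds toxic at the top doses (ATP drop 0.5 log10)."""
    return [ToxicitySpec(f"C{i:04d}", 2.0, 0.5) for i in range(16, 21)]


def _default_controls() -> dict[str, int]:
    # 24 vehicle (6 per stimulation-order role) + 8 no-cell per plate.
    d = {r.value: 6 for r in VEHICLE_ROLES}
    d[ControlRole.NO_CELL.value] = 8
    return d


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults reproduce the screen's design: 3 donor replicates, 5 plates
    per donor, a 384-well (16x24) geometry, 433 compounds annotated to
    184 targets at doses 0.08/0.4/2/10 uM, with interspersed vehicle and
    no-cell control wells.
    """

    seed: int = 0
    donors: int = 3
    plates_per_donor: int = 5
    geometry: tuple[int, int] = (16, 24)
    n_compounds: int = 433
    n_targets: int = 184
    doses_uM: tuple[float, ...] = (0.08, 0.4, 2.0, 10.0)
    controls_per_plate: dict[str, int] = field(default_factory=_default_controls)
    baseline_log10: dict[str, float] = field(
        default_factory=lambda: {"ATP": 5.0, "LYZ.NS": 4.0, "LYZ.S": 4.0}
    )
    background_log10: dict[str, float] = field(
        default_factory=lambda: {"ATP": 3.5, "LYZ.NS": 3.2, "LYZ.S": 3.2}
    )
    noise_sd_log10: dict[str, float] = field(
        default_factory=lambda: {"ATP": 0.08, "LYZ.NS": 0.10, "LYZ.S": 0.10}
    )
    plate_offset_sd_log10: float = 0.05
    spatial_amplitude_log10: float = 0.05
    stim_effect_log10: float = 0.3
    hit_spec: list[HitSpec] = field(default_factory=default_hit_spec)
    toxicity_spec: list[ToxicitySpec] = field(default_factory=default_toxicity_spec)

    def __post_init__(self) -> None:
        for sd in self.noise_sd_log10.values():
            if not sd > 0:
                raise ValueError("noise_sd_log10 must be positive")
        for h in self.hit_spec:
            if not np.isfinite(h.beta):
                raise ValueError(f"non-finite true SSMD for {h.treatment_id}")

    def treatment_ids(self) -> list[str]:
        return [f"C{i:04d}" for i in range(1, self.n_compounds + 1)]

    def target_map(self) -> dict[str, str]:
        """Round-robin compound -> target annotation (n_targets unique)."""
        return {
            t: f"T{(i % self.n_targets) + 1:03d}"
            for i, t in enumerate(self.treatment_ids())
        }

    def to_provenance(self) -> dict:
        d = asdict(self)
        d["hit_spec"] = [asdict(h) for h in self.hit_spec]
        d["toxicity_spec"] = [asdict(t) for t in self.toxicity_spec]
        return d


@dataclass
class TruthTable:
    """Ground truth of a simulated screen.

    ``effects``: per (treatment, dose, assay) the planted log10 effect
    and true SSMD. ``spatial``: per (donor, plate, row, col, assay) the
    spatial offset added to that well.
    """

    effects: pd.DataFrame
    spatial: pd.DataFrame


def _effect_lookup(
    config: SimulationConfig, doses: Sequence[float]
) -> tuple[dict[tuple[str, float, str], float], pd.DataFrame]:
    """Planted log10 effect per (treatment, dose, assay) and the truth frame."""
    effects: dict[tuple[str, float, str], float] = {}
    for h in config.hit_spec:
        assays = ["LYZ.NS", "LYZ.S"] if h.assay == "LYZ.BOTH" else [h.assay]
        for assay in assays:
            sd = config.noise_sd_log10[assay]
            for dose in doses:
                eff = h.beta * sd * float(h.response(dose))
                key = (h.treatment_id, float(dose), assay)
                effects[key] = effects.get(key, 0.0) + eff
    for t in config.toxicity_spec:
        for dose in doses:
            if dose >= t.dose_threshold_uM:
                key = (t.treatment_id, float(dose), "ATP")
                effects[key] = effects.get(key, 0.0) - t.atp_drop_log10
    rows = []
    for tid in sorted({k[0] for k in effects}):
        for dose in doses:
            for assay in _ASSAYS:
                eff = effects.get((tid, float(dose), assay), 0.0)
                rows.append(
                    {
                        "treatment_id": tid,
                        "dose_uM": float(dose),
                        "assay": assay,
                        "true_effect_log10": eff,
                        "true_ssmd": eff / config.noise_sd_log10[assay],
                    }
                )
    truth = pd.DataFrame(
        rows,
        columns=["treatment_id", "dose_uM", "assay", "true_effect_log10", "true_ssmd"],
    )
    return effects, truth


def _spatial_surface(
    rng: np.random.Generator, geometry: tuple[int, int], amplitude: float
) -> np.ndarray:
    """Low-order polynomial ramp plus an edge offset, in log10 units."""
    n_rows, n_cols = geometry
    u = (np.arange(n_rows) - (n_rows - 1) / 2) / max(n_rows - 1, 1)
    v = (np.arange(n_cols) - (n_cols - 1) / 2) / max(n_cols - 1, 1)
    U, V = np.meshgrid(u, v, indexing="ij")
    c = rng.uniform(-1.0, 1.0, size=5)
    surface = amplitude * (c[0] * U + c[1] * V + c[2] * U * V + c[3] * U**2 + c[4] * V**2)
    edge = np.zeros((n_rows, n_cols), dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    surface = surface + rng.uniform(-0.5, 0.5) * amplitude * edge
    return surface


def _build_plate_layout(
    rng: np.random.Generator,
    config: SimulationConfig,
    plate_ids: Sequence[str],
    condition_list: Sequence[tuple[str, float]],
    wells_per_condition_per_plate: int | None,
    controls_per_plate: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assign roles/treatments to wells.

    ``wells_per_condition_per_plate=None`` pools compound slots across
    plates and scatters each (treatment, dose) once at random (primary
    screen); an integer places that many wells of every condition on
    every plate (validation screen). Leftover wells become extra vehicle
    wells cycling roles A-D so every well carries a record.
    """
    n_rows, n_cols = config.geometry
    if controls_per_plate is None:
        controls_per_plate = config.controls_per_plate
    layouts = []
    free_slots: list[tuple[str, int, int]] = []
    for plate in plate_ids:
        slots = [(plate, r + 1, c + 1) for r in range(n_rows) for c in range(n_cols)]
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]
        pos = 0
        for role, count in controls_per_plate.items():
            for _ in range(count):
                if pos >= len(slots):
                    raise ValueError(f"plate {plate}: control wells exceed capacity")
                p, r, c = slots[pos]
                layouts.append((p, r, c, role, "", np.nan))
                pos += 1
        free_slots.extend(slots[pos:])

    if wells_per_condition_per_plate is None:
        needed = len(condition_list)
    else:
        needed = len(condition_list) * wells_per_condition_per_plate * len(plate_ids)
    if needed > len(free_slots):
        raise ValueError(
            f"plate capacity exceeded: {needed} compound wells requested, "
            f"{len(free_slots)} free wells available"
        )

    if wells_per_condition_per_plate is None:
        order = rng.permutation(len(free_slots))
        for i, (tid, dose) in enumerate(condition_list):
            p, r, c = free_slots[order[i]]
            layouts.append((p, r, c, ControlRole.COMPOUND.value, tid, dose))
        used = set(order[: len(condition_list)])
        leftovers = [s for i, s in enumerate(free_slots) if i not in used]
    else:
        leftovers = []
        by_plate: dict[str, list[tuple[str, int, int]]] = {}
        for s in free_slots:
            by_plate.setdefault(s[0], []).append(s)
        for plate in plate_ids:
            slots = by_plate.get(plate, [])
            k = 0
            for tid, dose in condition_list:
                for _ in range(wells_per_condition_per_plate):
                    p, r, c = slots[k]
                    layouts.append((p, r, c, ControlRole.COMPOUND.value, tid, dose))
                    k += 1
            leftovers.extend(slots[k:])

    for i, (p, r, c) in enumerate(leftovers):
        role = VEHICLE_ROLES[i % 4].value
        layouts.append((p, r, c, role, "", np.nan))

    return pd.DataFrame(
        layouts, columns=["plate", "well_row", "well_col", "role", "treatment_id", "dose_uM"]
    )


def _realize_values(
    rng: np.random.Generator,
    config: SimulationConfig,
    layout: pd.DataFrame,
    donor: str,
    effects: Mapping[tuple[str, float, str], float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a layout to well x assay records with simulated raw values."""
    frames = []
    spatial_rows = []
    for plate in sorted(layout["plate"].unique()):
        sub = layout[layout["plate"] == plate]
        for assay in _ASSAYS:
            surface = _spatial_surface(rng, config.geometry, config.spatial_amplitude_log10)
            plate_offset = rng.normal(0.0, config.plate_offset_sd_log10)
            rows = sub["well_row"].to_numpy() - 1
            cols = sub["well_col"].to_numpy() - 1
            role = sub["role"].to_numpy()
            is_no_cell = role == ControlRole.NO_CELL.value
            base = np.where(
                is_no_cell,
                config.background_log10[assay],
                config.baseline_log10[assay],
            )
            stim = np.zeros(len(sub))
            if assay == "LYZ.NS":
                stim[np.isin(role, list(STIMULATED_IN_NS))] = config.stim_effect_log10
            elif assay == "LYZ.S":
                stim[np.isin(role, list(STIMULATED_IN_S))] = config.stim_effect_log10
            eff = np.array(
                [
                    effects.get((t, float(d), assay), 0.0)
                    if isinstance(t, str) and t
                    else 0.0
                    for t, d in zip(sub["treatment_id"], sub["dose_uM"])
                ]
            )
            noise = rng.normal(0.0, config.noise_sd_log10[assay], size=len(sub))
            log10_value = base + plate_offset + surface[rows, cols] + stim + eff + noise
            frame = sub.copy()
            frame["assay"] = assay
            frame["raw_value"] = np.power(10.0, log10_value)
            frame["donor"] = donor
            frames.append(frame)
            spatial_rows.append(
                pd.DataFrame(
                    {
                        "donor": donor,
                        "plate": plate,
                        "well_row": sub["well_row"].to_numpy(),
                        "well_col": sub["well_col"].to_numpy(),
                        "assay": assay,
                        "spatial_offset_log10": surface[rows, cols],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True), pd.concat(spatial_rows, ignore_index=True)


def _finish_dataset(
    frames: list[pd.DataFrame],
    config: SimulationConfig,
    screen_id: str,
    target_map: Mapping[str, str],
) -> ScreenDataset:
    frame = pd.concat(frames, ignore_index=True)
    frame["screen_id"] = screen_id
    frame["target_annotation"] = frame["treatment_id"].map(
        lambda t: target_map.get(t, "") if t else ""
    )
    frame = frame[WELL_TABLE_COLUMNS]
    return ScreenDataset(
        frame,
        geometry=config.geometry,
        provenance={"screen_id": screen_id, "config": config.to_provenance()},
    )


def generate_primary_screen(
    config: SimulationConfig,
) -> tuple[ScreenDataset, TruthTable]:
    """Simulate the primary screen.

    Each donor replicate scatters every (compound, dose) pair once at
    random across its plates; every plate carries the configured control
    wells plus extra vehicle fill, so each plate x assay yields a full
    grid of records. Deterministic given ``config.seed``.

    Draw order per donor: well placement, then per plate x assay the
    spatial surface, plate offset and well noise.
    """
    rng = np.random.default_rng(config.seed)
    tids = config.treatment_ids()
    if len(set(tids)) != len(tids):
        raise ValueError("duplicate treatment ids")
    conditions = [(t, float(d)) for t in tids for d in config.doses_uM]
    effects, truth_effects = _effect_lookup(config, config.doses_uM)
    frames, spatials = [], []
    for d in range(1, config.donors + 1):
        donor = f"m{d}"
        plate_ids = [f"{donor}-P{p}" for p in range(1, config.plates_per_donor + 1)]
        layout = _build_plate_layout(rng, config, plate_ids, conditions, None)
        values, spatial = _realize_values(rng, config, layout, donor, effects)
        frames.append(values)
        spatials.append(spatial)
    dataset = _finish_dataset(frames, config, "primary", config.target_map())
    return dataset, TruthTable(truth_effects, pd.concat(spatials, ignore_index=True))


def generate_validation_screen(
    config: SimulationConfig,
    hits: Sequence[tuple[str, float]],
    n_plates: int = 4,
    wells_per_dose_per_plate: int = 2,
    controls_per_plate: Mapping[str, int] | None = None,
) -> tuple[ScreenDataset, TruthTable]:
    """Simulate the confirmatory screen for a list of (treatment,
    optimal dose) pairs.

    Each treatment is re-tested at twofold above, at, twofold below and
    fourfold below its optimal dose, with ``wells_per_dose_per_plate``
    wells on each of ``n_plates`` replicate plates (defaults give the
    n=8 well replicates per dose). Plates carry large vehicle blocks
    (default 25 wells per stimulation-order role, so 100 vehicle wells
    feed the ATP control median and 25 role-A wells the LYZ.S one),
    configurable via ``controls_per_plate``.
    """
    if not hits:
        raise ValueError("validation screen requires a nonempty hit list")
    conditions = []
    all_doses: set[float] = set()
    for tid, opt in hits:
        for mult in (2.0, 1.0, 0.5, 0.25):
            conditions.append((tid, float(opt * mult)))
            all_doses.add(float(opt * mult))
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate (treatment, dose) conditions in hit list")
    rng = np.random.default_rng(config.seed)
    effects, truth_effects = _effect_lookup(config, sorted(all_doses))
    plate_ids = [f"v-P{p}" for p in range(1, n_plates + 1)]
    if controls_per_plate is None:
        controls_per_plate = {r.value: 25 for r in VEHICLE_ROLES}
        controls_per_plate[ControlRole.NO_CELL.value] = config.controls_per_plate.get(
            ControlRole.NO_CELL.value, 8
        )
    layout = _build_plate_layout(
        rng, config, plate_ids, conditions, wells_per_dose_per_plate, controls_per_plate
    )
    values, spatial = _realize_values(rng, config, layout, "v1", effects)
    dataset = _finish_dataset([values], config, "validation", config.target_map())
    return dataset, TruthTable(truth_effects, spatial)


def generate_composition_counts(
    seed: int,
    n_timepoints: int,
    base_fractions: Mapping[str, float],
    designed_or: Mapping[tuple[str, int], float] | None = None,
    cells_per_sample: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial cell-composition time course for control vs treated.

    Control samples draw from ``base_fractions``. Treated fractions come
    from the multiplicative tilt ``q_t = OR_t p_t / sum_u OR_u p_u``
    with designed odds ratios keyed by (cell_type, timepoint); with a
    single non-unit OR this reproduces the (type vs rest) odds transform
    exactly (e.g. p=0.2, OR=2 -> q=1/3) and the tilted fractions always
    sum to 1. The returned truth table carries both the designed OR and
    the realized (type vs rest) OR of the tilted fractions.

    Returns (composition table, truth table); deterministic given seed.
    """
    p = np.array([base_fractions[t] for t in base_fractions], dtype=float)
    types = list(base_fractions)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"base fractions must sum to 1 (got {p.sum()!r})")
    if (p < 0).any():
        raise ValueError("base fractions must be nonnegative")
    designed_or = dict(designed_or or {})
    for (_, _), v in designed_or.items():
        if not v > 0:
            raise ValueError("designed odds ratios must be positive")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for tp in range(n_timepoints):
        ors = np.array([designed_or.get((t, tp), 1.0) for t in types])
        q = ors * p
        q = q / q.sum()
        n_control = rng.multinomial(cells_per_sample, p)
        n_treated = rng.multinomial(cells_per_sample, q)
        for i, t in enumerate(types):
            rows.append(("control", tp, t, int(n_control[i])))
            rows.append(("treated", tp, t, int(n_treated[i])))
            realized = (q[i] / (1 - q[i])) / (p[i] / (1 - p[i])) if 0 < q[i] < 1 and 0 < p[i] < 1 else np.nan
            truth_rows.append((t, tp, float(ors[i]), float(realized), float(p[i]), float(q[i])))
    table = pd.DataFrame(rows, columns=["condition", "timepoint", "cell_type", "n_cells"])
    table.insert(0, "sample_id", table["condition"] + "-t" + table["timepoint"].astype(str))
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell_type", "timepoint", "designed_or", "realized_or",
                 "control_fraction", "treated_fraction"],
    )
    return table, truth
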