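"""Drug-screen summaries, nonparametric tests, and seeding schedules.

Dose-response tables hold per-well contraction amplitudes for compounds at
several doses plus vehicle-control wells.  Effects are reported as the
relative change in contraction amplitude versus vehicle, normalised within
each independent experiment and then aggregated across experiments, with
pairwise Mann-Whitney U tests against the pooled vehicle group.

Also included: the robotic dispense schedule generator — a plate's wells
are seeded in fixed-capacity batches (16 wells at a time for a 96-well
plate, i.e. 6 batches) with four droplets placed at the north, east, south
and west positions of each well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DOSE_TABLE_COLUMNS",
    "SeedingPlan",
    "WellSeeding",
    "mann_whitney_u",
    "summarize_dose_response",
    "relative_change",
    "seeding_plan",
    "load_dose_table",
]

DOSE_TABLE_COLUMNS = ["well", "compound", "dose_molar", "amplitude_um", "experiment"]

DROP_POSITIONS = ("north", "east", "south", "west")


def _is_vehicle(dose) -> bool:
    if isinstance(dose, str):
        return dose.strip().lower() == "vehicle"
    return float(dose) == 0.0


def load_dose_table(path) -> pd.DataFrame:
    """Read a `well,compound,dose_molar,amplitude_um,experiment` CSV.

    ``dose_molar`` is numeric molar concentration, with 0 or the string
    ``"vehicle"`` marking control wells.
    """
    df = pd.read_csv(path)
    missing = set(DOSE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dose table is missing columns {sorted(missing)}")
    return df


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, exact_threshold: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U reported for sample ``x``.

    The exact null distribution is enumerated when both samples are small
    (``max(n1, n2) <= exact_threshold``) and tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if max(len(x), len(y)) <= exact_threshold and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def relative_change(dose_center: float, vehicle_center: float) -> float:
    """Relative change of a dose-group centre versus the vehicle centre."""
    if vehicle_center == 0:
        raise ValueError("vehicle centre is zero; relative change undefined")
    return (dose_center - vehicle_center) / vehicle_center


def summarize_dose_response(
    table: pd.DataFrame,
    metric: str = "amplitude_um",
    center: str = "mean",
    exact_threshold: int = 8,
    holm_adjust: bool = False,
) -> pd.DataFrame:
    """Per (compound, dose) summary of relative change versus vehicle.

    Normalisation is per experiment: each dose group's centre within an
    experiment is compared to that experiment's vehicle centre, and the
    per-experiment relative changes are then aggregated across experiments
    with the same centre statistic.  ``center`` selects mean ± SD or
    median ± MAD (median absolute deviation, unscaled).  The U test
    compares pooled dose amplitudes with the pooled vehicle amplitudes;
    p-values are unadjusted, with an optional Holm-adjusted column.
    """
    if center == "mean":
        ctr, spr = np.mean, np.std
    elif center == "median":
        ctr = np.median
        spr = lambda v: stats.median_abs_deviation(v, scale=1.0)  # noqa: E731
    else:
        raise ValueError("center must be 'mean' or 'median'")
    df = table.copy()
    df["_vehicle"] = df["dose_molar"].map(_is_vehicle)
    veh_by_exp: dict = {}
    for exp, sub in df[df["_vehicle"]].groupby("experiment"):
        c = float(ctr(sub[metric]))
        if c == 0:
            raise ValueError(f"vehicle centre is zero in experiment {exp!r}")
        veh_by_exp[exp] = c
    if not veh_by_exp:
        raise ValueError("no vehicle wells in the table")
    vehicle_pooled = df.loc[df["_vehicle"], metric].to_numpy()
    rows = []
    dosed = df[~df["_vehicle"]].assign(
        dose_molar=lambda s: s["dose_molar"].astype(float)
    )
    for (compound, dose), sub in dosed.groupby(["compound", "dose_molar"], sort=True):
        per_exp = []
        for exp, esub in sub.groupby("experiment"):
            if exp not in veh_by_exp:
                raise ValueError(f"experiment {exp!r} has no vehicle wells")
            per_exp.append(
                relative_change(float(ctr(esub[metric])), veh_by_exp[exp])
            )
        values = sub[metric].to_numpy()
        u, p = mann_whitney_u(values, vehicle_pooled, exact_threshold=exact_threshold)
        rows.append(
            {
                "compound": compound,
                "dose": dose,
                "relative_change": float(ctr(per_exp)),
                "center": float(ctr(values)),
                "spread": float(spr(values)),
                "n": len(values),
                "U": u,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).sort_values(["compound", "dose"]).reset_index(drop=True)
    if holm_adjust and len(out):
        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


@dataclass(frozen=True)
class WellSeeding:
    well: str
    drops: tuple[tuple[str, float], ...]  # (position, volume_ul)


@dataclass
class SeedingPlan:
    """Ordered dispense batches covering every destination well once."""

    batches: list[list[WellSeeding]]
    batch_size: int
    drop_volume_ul: float

    @property
    def n_wells(self) -> int:
        return sum(len(b) for b in self.batches)

    def wells(self) -> list[str]:
        return [ws.well for batch in self.batches for ws in batch]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, batch in enumerate(self.batches, start=1):
            for ws in batch:
                for pos, vol in ws.drops:
                    rows.append(
                        {"batch": bi, "well": ws.well, "position": pos,
                         "volume_ul": vol}
                    )
        return pd.DataFrame(rows)


def seeding_plan(
    n_wells: int,
    batch_size: int = 16,
    drops_per_well: int = 4,
    drop_volume_ul: float = 2.5,
    plate_rows: int = 8,
    plate_cols: int = 12,
) -> SeedingPlan:
    """Batch dispense schedule in plate row-major order (A1, A2, ...).

    ``ceil(n_wells / batch_size)`` batches; drop positions cycle through
    north, east, south, west.  A 96-well plate at 16 wells per batch gives
    6 batches.
    """
    if min(n_wells, batch_size, drops_per_well) < 1 or drop_volume_ul <= 0:
        raise ValueError("all plan parameters must be positive")
    if n_wells > plate_rows * plate_cols:
        raise ValueError(
            f"{n_wells} wells do not fit a {plate_rows}x{plate_cols} plate"
        )
    wells = [
        f"{chr(ord('A') + r)}{c + 1}"
        for r in range(plate_rows)
        for c in range(plate_cols)
    ][:n_wells]
    drops = tuple(
        (DROP_POSITIONS[i % len(DROP_POSITIONS)], drop_volume_ul)
        for i in range(drops_per_well)
    )
    seedings = [WellSeeding(well=w, drops=drops) for w in wells]
    batches = [
        seedings[i : i + batch_size] for i in range(0, len(seedings), batch_size)
    ]
    return SeedingPlan(
        batches=batches, batch_size=batch_size, drop_volume_ul=drop_volume_ul
    )
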