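"""Franz diffusion-cell reduction: mass balance, percents and diffusion rates.

Static (Franz) diffusion cells expose piglet skin to a metal cutting fluid
(MCF) donor.  At the end of each exposure (2, 4 or 24 h) three compartments
are assayed: remaining donor (plus donor rinses), the skin punch scaled to
the exposed area, and the receptor medium (plus its acid rinse).  Amounts
are normalised by the exposed area (0.64 cm2 orifice) and expressed as a
percent of the applied dose — the mean of triplicate t = 0 donor-matrix
samples for that MCF.  A time-averaged diffusion rate is the cumulative
receptor amount divided by exposure time.

Cells failing the trans-epidermal water loss (TEWL) barrier-integrity gate
(>= 10 g m-2 h-1) are excluded from reduction, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nonparametric import TestResult, kruskal_wallis

__all__ = [
    "DEFAULT_EXPOSED_AREA",
    "TEWL_LIMIT",
    "FranzCellRun",
    "check_barrier_integrity",
    "per_area",
    "percent_of_applied",
    "average_diffusion_rate",
    "mean_over_mcfs",
    "reduce_cells",
    "absorption_fraction",
    "reservoir_trend",
]

log = logging.getLogger(__name__)

DEFAULT_EXPOSED_AREA = 0.64  # cm2, 9-mm orifice (rounded study value)
TEWL_LIMIT = 10.0            # g m-2 h-1, strict upper bound for acceptance
COMPARTMENTS = ("donor", "skin", "receptor")


@dataclass(frozen=True)
class FranzCellRun:
    """One diffusion cell at its terminal sampling time."""

    cell_id: str
    mcf_id: str
    piglet_id: str
    exposure_time: float               # h
    donor_mass: float                  # ug, remaining donor + rinses
    skin_mass: float                   # ug, punch scaled to exposed area
    receptor_mass: float               # ug, receptor media + acid rinse
    exposed_area: float = DEFAULT_EXPOSED_AREA  # cm2
    tewl_before: float | None = None   # g m-2 h-1
    skin_thickness: float | None = None  # mm

    def __post_init__(self) -> None:
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be > 0")
        if self.exposed_area <= 0:
            raise ValueError("exposed_area must be > 0")
        for name in ("donor_mass", "skin_mass", "receptor_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def check_barrier_integrity(tewl: float, limit: float = TEWL_LIMIT) -> bool:
    """True iff the pre-exposure TEWL is strictly below the limit."""
    if tewl < 0:
        raise ValueError("TEWL must be >= 0")
    return tewl < limit


def per_area(mass: float, area: float = DEFAULT_EXPOSED_AREA) -> float:
    """Mass (ug) over exposed area (cm2) -> ug cm-2."""
    if area <= 0:
        raise ValueError("area must be > 0")
    return mass / area


def percent_of_applied(compartment: float, applied: float) -> float:
    """Compartment amount as percent of the applied area dose."""
    if applied <= 0:
        raise ValueError("applied dose must be > 0")
    return 100.0 * compartment / applied


def average_diffusion_rate(receptor: float, time: float) -> float:
    """Time-averaged diffusion rate in ng cm-2 h-1.

    ``receptor`` is the cumulative per-area receptor amount (ug cm-2) in
    the single terminal sample; no intermediate sampling occurs, so this
    is an average rate over the whole exposure, not an instantaneous flux.
    """
    if time <= 0:
        raise ValueError("time must be > 0")
    if receptor < 0:
        raise ValueError("receptor amount must be >= 0")
    return 1000.0 * receptor / time


def mean_over_mcfs(values) -> float:
    """Unweighted arithmetic mean of per-MCF quantities."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    return float(arr.mean())


def _applied_doses(mcf_matrix: pd.DataFrame) -> pd.Series:
    """Per-MCF applied area dose: mean of the triplicate t=0 matrix samples."""
    required = {"mcf_id", "applied_ug_per_cm2"}
    if not required <= set(mcf_matrix.columns):
        raise ValueError(f"mcf matrix needs columns {sorted(required)}")
    applied = mcf_matrix.groupby("mcf_id")["applied_ug_per_cm2"].mean()
    if (applied <= 0).any():
        bad = applied[applied <= 0].index.tolist()
        raise ValueError(f"non-positive applied dose for MCF(s) {bad}")
    return applied


def reduce_cells(
    runs: list[FranzCellRun] | pd.DataFrame,
    mcf_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Reduce replicate cells to a per-(MCF, time) mass balance table.

    Cells with a recorded TEWL failing the barrier gate are dropped (and
    logged).  Within each (mcf_id, exposure_time) group the per-area
    compartment amounts are averaged over replicates, then expressed as a
    percent of the MCF's applied dose; the receptor amount also yields the
    average diffusion rate.

    Returns a frame indexed by (mcf_id, time_h) with columns
    ``{donor,skin,receptor}_ug_cm2``, ``{donor,skin,receptor}_pct``,
    ``recovery_pct``, ``rate_ng_cm2_h`` and ``n``.
    """
    if isinstance(runs, pd.DataFrame):
        runs = [
            FranzCellRun(
                cell_id=str(r["cell_id"]),
                mcf_id=str(r["mcf_id"]),
                piglet_id=str(r.get("piglet_id", "")),
                exposure_time=float(r["time_h"]),
                exposed_area=float(r.get("area_cm2", DEFAULT_EXPOSED_AREA)),
                donor_mass=float(r["donor_ug"]),
                skin_mass=float(r["skin_ug"]),
                receptor_mass=float(r["receptor_ug"]),
                tewl_before=float(r["tewl"]) if pd.notna(r.get("tewl")) else None,
                skin_thickness=float(r["thickness_mm"]) if pd.notna(r.get("thickness_mm")) else None,
            )
            for _, r in runs.iterrows()
        ]
    if not runs:
        raise ValueError("no diffusion-cell runs supplied")

    kept = []
    for run in runs:
        if run.tewl_before is not None and not check_barrier_integrity(run.tewl_before):
            log.warning(
                "cell %s excluded: TEWL %.1f g m-2 h-1 >= %.0f",
                run.cell_id, run.tewl_before, TEWL_LIMIT,
            )
            continue
        kept.append(run)
    if not kept:
        raise ValueError("all cells failed the barrier-integrity gate")

    applied = _applied_doses(mcf_matrix)

    rows = []
    frame = pd.DataFrame(
        {
            "mcf_id": [r.mcf_id for r in kept],
            "time_h": [r.exposure_time for r in kept],
            "area": [r.exposed_area for r in kept],
            "donor": [per_area(r.donor_mass, r.exposed_area) for r in kept],
            "skin": [per_area(r.skin_mass, r.exposed_area) for r in kept],
            "receptor": [per_area(r.receptor_mass, r.exposed_area) for r in kept],
        }
    )
    for (mcf, t), grp in frame.groupby(["mcf_id", "time_h"], sort=True):
        if grp["area"].nunique() > 1:
            log.warning("mixed exposed areas within group (%s, %s h)", mcf, t)
        if mcf not in applied.index:
            raise ValueError(f"no donor-matrix entry for MCF {mcf!r}")
        a = float(applied.loc[mcf])
        row = {"mcf_id": mcf, "time_h": t, "n": len(grp), "applied_ug_cm2": a}
        for comp in COMPARTMENTS:
            amt = float(grp[comp].mean())
            row[f"{comp}_ug_cm2"] = amt
            row[f"{comp}_pct"] = percent_of_applied(amt, a)
        row["recovery_pct"] = sum(row[f"{c}_pct"] for c in COMPARTMENTS)
        row["rate_ng_cm2_h"] = average_diffusion_rate(row["receptor_ug_cm2"], t)
        rows.append(row)
    return pd.DataFrame(rows).set_index(["mcf_id", "time_h"]).sort_index()


def balance_from_means(amounts: pd.DataFrame) -> pd.DataFrame:
    """Mass-balance table from per-(MCF, time) *mean* amounts.

    ``amounts`` is tidy with columns mcf_id, compartment, time_h,
    amount_ug_cm2 (and optionally n); rows with ``compartment ==
    "matrix"`` at t = 0 carry the applied dose.  Output schema matches
    :func:`reduce_cells`.  This is the entry point when only group means
    are available rather than per-cell runs.
    """
    required = {"mcf_id", "compartment", "time_h", "amount_ug_cm2"}
    if not required <= set(amounts.columns):
        raise ValueError(f"amounts table needs columns {sorted(required)}")
    matrix = amounts[amounts["compartment"] == "matrix"]
    if matrix.empty:
        raise ValueError("no 'matrix' rows carrying the applied dose")
    applied = matrix.groupby("mcf_id")["amount_ug_cm2"].mean()

    rows = []
    body = amounts[amounts["compartment"].isin(COMPARTMENTS)]
    for (mcf, t), grp in body.groupby(["mcf_id", "time_h"], sort=True):
        if mcf not in applied.index:
            raise ValueError(f"no matrix entry for MCF {mcf!r}")
        a = float(applied.loc[mcf])
        row = {"mcf_id": mcf, "time_h": t, "applied_ug_cm2": a}
        if "n" in grp.columns:
            row["n"] = int(grp["n"].iloc[0])
        for comp in COMPARTMENTS:
            sel = grp[grp["compartment"] == comp]
            if len(sel) != 1:
                raise ValueError(f"expected one {comp} row for ({mcf}, {t} h)")
            amt = float(sel["amount_ug_cm2"].iloc[0])
            row[f"{comp}_ug_cm2"] = amt
            row[f"{comp}_pct"] = percent_of_applied(amt, a)
        row["recovery_pct"] = sum(row[f"{c}_pct"] for c in COMPARTMENTS)
        row["rate_ng_cm2_h"] = average_diffusion_rate(row["receptor_ug_cm2"], t)
        rows.append(row)
    return pd.DataFrame(rows).set_index(["mcf_id", "time_h"]).sort_index()


def absorption_fraction(balance: pd.DataFrame, time_h: float) -> float:
    """Across-MCF mean receptor percent-of-applied at one exposure time.

    Expressed as the percent value itself (e.g. 0.00197 meaning
    0.00197 %); this is the skin-absorption parameter the exposure
    scenario consumes as a dimensionless fraction.
    """
    sel = balance.xs(time_h, level="time_h")["receptor_pct"]
    return mean_over_mcfs(sel.to_numpy())


def reservoir_trend(skin_amounts_by_time: dict[float, list[float]]) -> TestResult:
    """Kruskal-Wallis comparison of skin amounts across exposure times.

    Tests whether the per-cell skin reservoir differs across the time
    groups; ``extra['increasing']`` records whether the group medians are
    nondecreasing with time (the reservoir build-up direction).
    """
    if len(skin_amounts_by_time) < 2:
        raise ValueError("need at least two time groups")
    times = sorted(skin_amounts_by_time)
    groups = [np.asarray(skin_amounts_by_time[t], dtype=float) for t in times]
    if any(g.size < 2 for g in groups):
        raise ValueError("each time group needs at least two cells")
    result = kruskal_wallis(groups)
    medians = [float(np.median(g)) for g in groups]
    increasing = all(b >= a for a, b in zip(medians, medians[1:]))
    extra = dict(result.extra, times=times, medians=medians, increasing=increasing)
    return TestResult(result.statistic, result.p_value, "kruskal-wallis-time-trend", extra=extra)
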