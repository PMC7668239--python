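"""Reduction of acid-wipe dermal samples to reference-corrected skin doses.

Workers' skin is sampled with nitric-acid-moistened wipes on six marked
surfaces (palm, wrist, index finger of each hand) after 2 h of normal work;
the little finger of the non-dominant hand is masked during the shift and
wiped as a per-worker clean-reference surface.  The pooled three-wipe
extract mass (ug Pb) is blank-corrected, normalised by the sampled area,
and reference-corrected to a skin dose in ug cm-2.

Censored measurements (below the limit of detection) follow the usual
LOD / sqrt(2) substitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AREAS",
    "WipeMeasurement",
    "SkinDose",
    "WorkerProfile",
    "compute_area_dose",
    "substitute_below_lod",
    "apply_reference_correction",
    "hand_sum",
    "hand_sums",
    "mean_skin_dose",
    "reduce_wipes",
]

HANDS = ("left", "right")
SITES = ("palm", "wrist", "index")
REFERENCE_SITE = "reference_little_finger"

#: Marked sampling areas in cm2: 3 x 3 cm on palm and wrist, 1 x 2 cm on
#: the index finger. The reference little finger uses the index-finger area.
DEFAULT_AREAS: Mapping[str, float] = {
    "palm": 9.0,
    "wrist": 9.0,
    "index": 2.0,
    REFERENCE_SITE: 2.0,
}


@dataclass(frozen=True)
class WipeMeasurement:
    """One pooled three-wipe extract from a marked skin surface."""

    worker_id: str
    hand: str
    site: str
    sampled_area: float          # cm2
    extract_mass: float          # ug Pb in the pooled extract
    blank_mass: float = 0.0      # ug Pb, mean of unused-wipe blanks
    below_lod: bool = False
    lod_mass: float | None = None  # ug, required when below_lod

    def __post_init__(self) -> None:
        if self.sampled_area <= 0:
            raise ValueError(f"sampled_area must be > 0, got {self.sampled_area}")
        if self.extract_mass < 0 or self.blank_mass < 0:
            raise ValueError("extract and blank masses must be >= 0")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}")
        if self.site not in SITES and self.site != REFERENCE_SITE:
            raise ValueError(f"unknown site {self.site!r}")


@dataclass(frozen=True)
class SkinDose:
    """Blank- and reference-corrected skin dose for one surface."""

    worker_id: str
    hand: str
    site: str
    dose: float  # ug cm-2

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class WorkerProfile:
    """One worker: end-of-shift blood Pb plus the six surface doses."""

    worker_id: str
    blood_pb: float              # ug dl-1 (LOD-substituted if censored)
    blood_below_lod: bool = False
    glove_use: bool = True
    doses: list[SkinDose] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.blood_pb < 0:
            raise ValueError("blood_pb must be >= 0")

    def dose(self, hand: str, site: str) -> SkinDose:
        matches = [d for d in self.doses if d.hand == hand and d.site == site]
        if len(matches) != 1:
            raise ValueError(
                f"worker {self.worker_id}: expected exactly one dose for "
                f"({hand}, {site}), found {len(matches)}"
            )
        return matches[0]


def compute_area_dose(m: WipeMeasurement) -> float:
    """Blank-corrected extract mass per sampled area, in ug cm-2.

    Blank subtraction precedes area normalisation; a blank exceeding the
    extract clamps to zero rather than going negative.
    """
    return max(0.0, m.extract_mass - m.blank_mass) / m.sampled_area


def substitute_below_lod(value: float, lod: float | None, below_lod: bool) -> float:
    """LOD / sqrt(2) substitution for censored values; identity otherwise."""
    if not below_lod:
        return value
    if lod is None or not lod > 0:
        raise ValueError("a censored value requires a positive LOD")
    return lod / math.sqrt(2.0)


def apply_reference_correction(dose: float, reference_dose: float) -> float:
    """Subtract the worker's clean-reference dose, clamping at zero."""
    if dose < 0 or reference_dose < 0:
        raise ValueError("doses must be >= 0")
    return max(0.0, dose - reference_dose)


def hand_sum(worker: WorkerProfile, hand: str) -> float:
    """Sum of palm + wrist + index doses (ug cm-2) for one hand."""
    if hand not in HANDS:
        raise ValueError(f"hand must be one of {HANDS}")
    return sum(worker.dose(hand, site).dose for site in SITES)


def hand_sums(doses: pd.DataFrame) -> pd.DataFrame:
    """Per-worker left/right hand dose sums from a tidy dose table.

    ``doses`` needs columns worker_id, hand, site, dose_ug_cm2 with the
    three sites present for each (worker, hand).
    """
    site_rows = doses[doses["site"].isin(SITES)]
    counts = site_rows.groupby(["worker_id", "hand"])["site"].nunique()
    if (counts != len(SITES)).any():
        bad = counts[counts != len(SITES)].index.tolist()
        raise ValueError(f"missing sites for worker/hand pairs: {bad}")
    table = site_rows.pivot_table(
        index="worker_id", columns="hand", values="dose_ug_cm2", aggfunc="sum"
    )
    return table[list(HANDS)]


def mean_skin_dose(
    workers: Iterable[WorkerProfile] | pd.DataFrame,
    exclude: Iterable[str] | None = None,
) -> float:
    """Unweighted arithmetic mean over all worker x hand x site dose values.

    Accepts either a collection of :class:`WorkerProfile` (6 doses each) or
    a tidy dose DataFrame.  ``exclude`` drops whole workers before
    averaging (e.g. the non-glove workers in a sensitivity analysis).
    Full precision is retained; rounding is presentation-only.
    """
    excluded = {str(w) for w in (exclude or ())}
    if isinstance(workers, pd.DataFrame):
        rows = workers[workers["site"].isin(SITES)]
        rows = rows[~rows["worker_id"].astype(str).isin(excluded)]
        values = rows["dose_ug_cm2"].to_numpy(dtype=float)
    else:
        values = np.array(
            [
                d.dose
                for w in workers
                if str(w.worker_id) not in excluded
                for d in w.doses
                if d.site in SITES
            ],
            dtype=float,
        )
    if values.size == 0:
        raise ValueError("no dose values selected")
    return float(values.mean())


def reduce_wipes(wipes: pd.DataFrame) -> pd.DataFrame:
    """Reduce a raw wipe table to reference-corrected skin doses.

    Input columns: worker_id, hand, site, area_cm2, extract_ug, blank_ug,
    below_lod, lod_ug.  Rows with ``site == "reference_little_finger"``
    provide the per-worker reference dose applied to all six surfaces of
    that worker (zero if absent).  Returns a tidy frame with columns
    worker_id, hand, site, dose_ug_cm2.
    """
    required = {"worker_id", "hand", "site", "area_cm2", "extract_ug"}
    missing = required - set(wipes.columns)
    if missing:
        raise ValueError(f"wipe table missing columns: {sorted(missing)}")

    records = []
    for _, row in wipes.iterrows():
        mass = substitute_below_lod(
            float(row["extract_ug"]),
            float(row["lod_ug"]) if "lod_ug" in row and pd.notna(row.get("lod_ug")) else None,
            bool(row.get("below_lod", False)),
        )
        m = WipeMeasurement(
            worker_id=str(row["worker_id"]),
            hand=str(row["hand"]),
            site=str(row["site"]),
            sampled_area=float(row["area_cm2"]),
            extract_mass=mass,
            blank_mass=float(row.get("blank_ug", 0.0) or 0.0),
        )
        records.append((m.worker_id, m.hand, m.site, compute_area_dose(m)))
    raw = pd.DataFrame(records, columns=["worker_id", "hand", "site", "dose_ug_cm2"])

    refs = (
        raw[raw["site"] == REFERENCE_SITE]
        .groupby("worker_id")["dose_ug_cm2"]
        .mean()
    )
    out = raw[raw["site"].isin(SITES)].copy()
    out["dose_ug_cm2"] = [
        apply_reference_correction(d, float(refs.get(w, 0.0)))
        for w, d in zip(out["worker_id"], out["dose_ug_cm2"])
    ]
    return out.reset_index(drop=True)
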