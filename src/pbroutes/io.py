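"""CSV schemas, study-bundle loading/validation and report rendering.

All files are plain UTF-8 CSV with a header row and dot decimal
separators.  Censoring is encoded as a boolean column plus an explicit
LOD column, never as ``"<x"`` strings inside numeric columns.  Rendering
is presentation-only: rounded report values never feed back into
computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .exposure import ExposureScenario

__all__ = [
    "SchemaError",
    "StudyBundle",
    "load_csv",
    "load_scenario",
    "load_bundle",
    "write_report",
]

log = logging.getLogger(__name__)

WIPE_COLUMNS = [
    "worker_id", "hand", "site", "area_cm2",
    "extract_ug", "blank_ug", "below_lod", "lod_ug",
]
WORKER_COLUMNS = ["worker_id", "blood_pb_ugdl", "blood_below_lod", "glove_use"]
DOSE_COLUMNS = ["worker_id", "hand", "site", "dose_ug_cm2"]
AIR_COLUMNS = ["worker_id", "air_ug_m3"]
FRANZ_RUN_COLUMNS = [
    "cell_id", "mcf_id", "piglet_id", "time_h", "area_cm2",
    "donor_ug", "skin_ug", "receptor_ug", "tewl", "thickness_mm",
]
MCF_MATRIX_COLUMNS = ["mcf_id", "replicate", "applied_ug_per_cm2"]

# columns whose physical values must never be negative, by schema
_NONNEGATIVE = {
    "area_cm2", "extract_ug", "blank_ug", "lod_ug", "dose_ug_cm2",
    "blood_pb_ugdl", "air_ug_m3", "time_h", "donor_ug", "skin_ug",
    "receptor_ug", "tewl", "applied_ug_per_cm2",
}


class SchemaError(ValueError):
    """A CSV file failed schema or integrity validation."""


@dataclass
class StudyBundle:
    """A fully parsed study: workers, doses/wipes, air and Franz data."""

    workers: pd.DataFrame
    doses: pd.DataFrame
    wipes: pd.DataFrame | None = None
    air: pd.DataFrame | None = None
    franz_runs: pd.DataFrame | None = None
    mcf_matrix: pd.DataFrame | None = None
    scenario: ExposureScenario = field(default_factory=ExposureScenario)


def load_csv(path: str | Path, required: list[str], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV and validate its header and value signs."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: file contains no data rows")
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col in _NONNEGATIVE:
            bad = df.index[pd.to_numeric(df[col], errors="coerce") < 0]
            if len(bad):
                raise SchemaError(
                    f"{path}: negative value in column {col!r} at row {int(bad[0]) + 2}"
                )
    for col in ("worker_id", "mcf_id", "cell_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def load_scenario(path: str | Path) -> ExposureScenario:
    """Read an exposure scenario from a YAML key-value file."""
    with open(path) as fh:
        params = yaml.safe_load(fh) or {}
    known = set(ExposureScenario.__dataclass_fields__)
    unknown = set(params) - known
    if unknown:
        raise SchemaError(f"{path}: unknown scenario parameters {sorted(unknown)}")
    return ExposureScenario(**params)


def _check_integrity(bundle: StudyBundle, where: Path) -> None:
    worker_ids = set(bundle.workers["worker_id"])
    for name, df in (("skin_doses", bundle.doses), ("wipes", bundle.wipes), ("air", bundle.air)):
        if df is None:
            continue
        orphans = df.loc[~df["worker_id"].isin(worker_ids)]
        if len(orphans):
            row = orphans.index[0] + 2
            raise SchemaError(
                f"{where / (name + '.csv')}: row {row} references unknown worker "
                f"{orphans['worker_id'].iloc[0]!r}"
            )
    if bundle.franz_runs is not None:
        if bundle.mcf_matrix is None:
            raise SchemaError(f"{where}: franz_runs.csv present without mcf_matrix.csv")
        known = set(bundle.mcf_matrix["mcf_id"])
        orphans = bundle.franz_runs.loc[~bundle.franz_runs["mcf_id"].isin(known)]
        if len(orphans):
            row = orphans.index[0] + 2
            raise SchemaError(
                f"{where / 'franz_runs.csv'}: row {row} references MCF "
                f"{orphans['mcf_id'].iloc[0]!r} with no matrix entry"
            )


def load_bundle(directory: str | Path, scenario: ExposureScenario | None = None) -> StudyBundle:
    """Load and validate a study directory.

    Expected files: ``workers.csv`` plus either ``skin_doses.csv`` or raw
    ``wipes.csv`` (reduced on load); optional ``air.csv``,
    ``franz_runs.csv`` + ``mcf_matrix.csv`` and ``scenario.yaml``.
    """
    from .wipes import reduce_wipes

    directory = Path(directory)
    workers = load_csv(directory / "workers.csv", WORKER_COLUMNS)

    wipes = None
    doses_path = directory / "skin_doses.csv"
    wipes_path = directory / "wipes.csv"
    if doses_path.exists():
        doses = load_csv(doses_path, DOSE_COLUMNS)
    elif wipes_path.exists():
        wipes = load_csv(wipes_path, WIPE_COLUMNS, optional=("blank_ug", "below_lod", "lod_ug"))
        doses = reduce_wipes(wipes)
        log.info("reduced %d wipes to %d doses", len(wipes), len(doses))
    else:
        raise SchemaError(f"{directory}: neither skin_doses.csv nor wipes.csv present")

    air = (
        load_csv(directory / "air.csv", AIR_COLUMNS)
        if (directory / "air.csv").exists()
        else None
    )
    franz_runs = (
        load_csv(directory / "franz_runs.csv", FRANZ_RUN_COLUMNS, optional=("tewl", "thickness_mm"))
        if (directory / "franz_runs.csv").exists()
        else None
    )
    mcf_matrix = (
        load_csv(directory / "mcf_matrix.csv", MCF_MATRIX_COLUMNS)
        if (directory / "mcf_matrix.csv").exists()
        else None
    )
    if scenario is None:
        scen_path = directory / "scenario.yaml"
        scenario = load_scenario(scen_path) if scen_path.exists() else ExposureScenario()

    bundle = StudyBundle(
        workers=workers, doses=doses, wipes=wipes, air=air,
        franz_runs=franz_runs, mcf_matrix=mcf_matrix, scenario=scenario,
    )
    _check_integrity(bundle, directory)
    log.info(
        "loaded bundle: %d workers, %d doses, franz=%s",
        len(workers), len(doses), "yes" if franz_runs is not None else "no",
    )
    return bundle


def _dose_matrix(doses: pd.DataFrame, workers: pd.DataFrame | None) -> pd.DataFrame:
    """Worker x (hand, site) dose matrix at report precision (1 decimal)."""
    wide = doses.pivot_table(
        index="worker_id", columns=["hand", "site"], values="dose_ug_cm2"
    )
    cols = [(h, s) for h in ("left", "right") for s in ("palm", "wrist", "index")]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    wide.columns = [f"{h}_{s}_ug_cm2" for h, s in cols]
    if workers is not None:
        wide.insert(0, "blood_pb_ugdl", workers.set_index("worker_id")["blood_pb_ugdl"])
    return wide.round(1)


def _mass_balance_text(balance: pd.DataFrame) -> pd.DataFrame:
    """Mass balance as 'amount (percent)' strings, compartment x time x MCF."""
    rows = []
    for comp in ("donor", "skin", "receptor"):
        for t in sorted(balance.index.get_level_values("time_h").unique()):
            row = {"compartment": comp, "time_h": t}
            for mcf in balance.index.get_level_values("mcf_id").unique():
                r = balance.loc[(mcf, t)]
                row[mcf] = f"{r[f'{comp}_ug_cm2']:.3g} ({r[f'{comp}_pct']:.3g})"
            rows.append(row)
    for t in sorted(balance.index.get_level_values("time_h").unique()):
        row = {"compartment": "avg_diffusion_rate_ng_cm2_h", "time_h": t}
        for mcf in balance.index.get_level_values("mcf_id").unique():
            row[mcf] = f"{balance.loc[(mcf, t), 'rate_ng_cm2_h']:.2g}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(results, outdir: str | Path) -> dict[str, Path]:
    """Render a fitted :class:`~pbroutes.model.LeadExposureResults`.

    Writes a dose matrix, a mass-balance table (if Franz data were
    fitted), the route table at report precision, and a JSON file with
    every unrounded quantity.  Missing stages are skipped with a log
    message rather than failing the report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if results.doses is not None:
        path = outdir / "dose_matrix.csv"
        _dose_matrix(results.doses, results.workers).to_csv(path)
        written["dose_matrix"] = path
    else:
        log.warning("report: no dose table available")

    if results.franz_balance is not None:
        path = outdir / "mass_balance.csv"
        _mass_balance_text(results.franz_balance).to_csv(path, index=False)
        written["mass_balance"] = path
    else:
        log.info("report: no diffusion-cell stage fitted")

    path = outdir / "routes.csv"
    results.routes.round(2).to_csv(path)
    written["routes"] = path

    path = outdir / "summary.txt"
    path.write_text(results.summary() + "\n")
    written["summary"] = path

    path = outdir / "results.json"
    path.write_text(json.dumps(results.to_dict(), indent=2, default=float))
    written["results_json"] = path
    return written
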