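"""Packaged study tables: worker doses and blood Pb, Franz-cell summaries.

The study's published measurements ship with the package as small CSV
files so every reduction and the full exposure assessment can be
reproduced without external input.  Blood Pb for the one censored worker
is stored as the detection limit with a flag; :func:`load_workers`
applies the LOD / sqrt(2) substitution by default.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exposure import ExposureScenario
from .wipes import substitute_below_lod

__all__ = [
    "load_workers",
    "load_skin_doses",
    "load_franz_amounts",
    "load_franz_percents",
    "load_franz_rates",
    "default_scenario",
]

GLOVE_FREE_WORKERS = ("3", "4")  # the two workers who did not wear gloves


def _read(name: str) -> pd.DataFrame:
    with resources.files("pbroutes.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_workers(substitute_lod: bool = True) -> pd.DataFrame:
    """Worker table: blood Pb (ug dl-1), censoring flag, glove use."""
    df = _read("workers.csv")
    df["worker_id"] = df["worker_id"].astype(str)
    if substitute_lod:
        df["blood_pb_ugdl"] = [
            substitute_below_lod(v, lod, flag)
            for v, lod, flag in zip(
                df["blood_pb_ugdl"], df["blood_lod_ugdl"], df["blood_below_lod"]
            )
        ]
    return df


def load_skin_doses() -> pd.DataFrame:
    """Tidy reference-corrected skin doses: 7 workers x 2 hands x 3 sites."""
    df = _read("skin_doses.csv")
    df["worker_id"] = df["worker_id"].astype(str)
    return df


def load_franz_amounts() -> pd.DataFrame:
    """Per-(MCF, compartment, time) mean amounts in ug cm-2.

    ``compartment == "matrix"`` rows at t = 0 are the applied doses.
    """
    return _read("franz_amounts.csv")


def load_franz_percents() -> pd.DataFrame:
    """Published percent-of-applied values (presentation precision)."""
    return _read("franz_percents.csv")


def load_franz_rates() -> pd.DataFrame:
    """Published per-MCF average diffusion rates (ng cm-2 h-1)."""
    return _read("franz_rates.csv")


def default_scenario() -> ExposureScenario:
    """The study's exposure scenario (packaged scenario.yaml)."""
    import yaml

    with resources.files("pbroutes.data").joinpath("scenario.yaml").open("r") as fh:
        params = yaml.safe_load(fh)
    return ExposureScenario(**params)
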