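"""Diffusion-cell reduction: barrier gate, mass balance, diffusion rates."""

import numpy as np
import pandas as pd
import pytest

from pbroutes import datasets, franz as F
from pbroutes.simulate import FranzSimParams, simulate_franz


@pytest.mark.parametrize("tewl, ok", [(4.2, True), (10.0, False), (15.1, False)])
def test_barrier_integrity_strict_threshold(tewl, ok):
    assert F.check_barrier_integrity(tewl) is ok


def test_barrier_integrity_rejects_negative():
    with pytest.raises(ValueError):
        F.check_barrier_integrity(-1.0)


@pytest.mark.parametrize(
    "mass, area, expected",
    [(0.00159, 0.64, 0.00248), (0.0, 0.64, 0.0), (6.4, 0.64, 10.0)],
)
def test_per_area(mass, area, expected):
    assert F.per_area(mass, area) == pytest.approx(expected, abs=5e-5)


@pytest.mark.parametrize(
    "amount, applied, expected",
    [(5.27, 48.4, 10.9), (9.00, 97.8, 9.20), (48.4, 48.4, 100.0)],
)
def test_percent_of_applied(amount, applied, expected):
    assert F.percent_of_applied(amount, applied) == pytest.approx(expected, abs=0.05)


def test_percent_of_applied_requires_positive_applied():
    with pytest.raises(ValueError):
        F.percent_of_applied(1.0, 0.0)


@pytest.mark.parametrize(
    "receptor, time, expected",
    [(0.00248, 2.0, 1.24), (0.0, 5.0, 0.0), (0.00306, 24.0, 0.1275)],
)
def test_average_diffusion_rate(receptor, time, expected):
    assert F.average_diffusion_rate(receptor, time) == pytest.approx(expected, abs=5e-4)


def test_mean_rate_across_mcfs_matches_reported():
    """The published per-MCF rates average to 0.78 / 0.41 / 0.11 ng cm-2 h-1."""
    rates = datasets.load_franz_rates()
    by_time = rates.groupby("interval_h")["rate_ng_cm2_h"].apply(list)
    assert F.mean_over_mcfs(by_time[2]) == pytest.approx(0.7875)
    assert F.mean_over_mcfs(by_time[4]) == pytest.approx(0.41)
    assert F.mean_over_mcfs(by_time[24]) == pytest.approx(0.107, abs=5e-3)
    assert F.mean_over_mcfs([3.3, 3.3]) == 3.3


def _runs(values, mcf="M1", time=2.0):
    rows = []
    for i, v in enumerate(values):
        rows.append(
            F.FranzCellRun(
                cell_id=f"c{i}", mcf_id=mcf, piglet_id="p", exposure_time=time,
                donor_mass=1.0, skin_mass=0.5, receptor_mass=v, tewl_before=5.0,
            )
        )
    return rows


def test_reduce_cells_averages_replicates_and_is_order_invariant():
    matrix = pd.DataFrame({"mcf_id": ["M1"] * 3, "replicate": [1, 2, 3],
                           "applied_ug_per_cm2": [290.0] * 3})
    runs = _runs([0.002 * 0.64, 0.004 * 0.64])
    fwd = F.reduce_cells(runs, matrix)
    rev = F.reduce_cells(runs[::-1], matrix)
    assert fwd.loc[("M1", 2.0), "receptor_ug_cm2"] == pytest.approx(0.003)
    pd.testing.assert_frame_equal(fwd, rev)


def test_reduce_cells_single_cell_is_identity():
    matrix = pd.DataFrame({"mcf_id": ["M1"], "replicate": [1], "applied_ug_per_cm2": [100.0]})
    run = F.FranzCellRun("c", "M1", "p", 4.0, donor_mass=60.0 * 0.64,
                         skin_mass=5.0 * 0.64, receptor_mass=0.01 * 0.64)
    out = F.reduce_cells([run], matrix)
    row = out.loc[("M1", 4.0)]
    assert row["donor_ug_cm2"] == pytest.approx(60.0)
    assert row["skin_pct"] == pytest.approx(5.0)
    assert row["rate_ng_cm2_h"] == pytest.approx(1000 * 0.01 / 4)


def test_reduce_cells_excludes_tewl_failures():
    matrix = pd.DataFrame({"mcf_id": ["M1"], "replicate": [1], "applied_ug_per_cm2": [100.0]})
    good = F.FranzCellRun("good", "M1", "p", 2.0, 1.0, 0.5, 0.002, tewl_before=4.0)
    bad = F.FranzCellRun("bad", "M1", "p", 2.0, 1.0, 0.5, 0.2, tewl_before=12.0)
    out = F.reduce_cells([good, bad], matrix)
    assert out.loc[("M1", 2.0), "n"] == 1
    assert out.loc[("M1", 2.0), "receptor_ug_cm2"] == pytest.approx(0.002 / 0.64)
    with pytest.raises(ValueError):
        F.reduce_cells([bad], matrix)


def test_reduce_cells_requires_matrix_entry_and_positive_applied():
    runs = _runs([0.001])
    with pytest.raises(ValueError):
        F.reduce_cells(runs, pd.DataFrame({"mcf_id": ["other"], "replicate": [1],
                                           "applied_ug_per_cm2": [10.0]}))
    with pytest.raises(ValueError):
        F.reduce_cells(runs, pd.DataFrame({"mcf_id": ["M1"], "replicate": [1],
                                           "applied_ug_per_cm2": [0.0]}))


def test_balance_from_study_means_spot_values(franz_balance):
    """Recomputed percents reproduce the published spot values."""
    assert franz_balance.loc[("MCF4", 24), "skin_pct"] == pytest.approx(10.9, abs=0.05)
    assert franz_balance.loc[("MCF3", 24), "skin_pct"] == pytest.approx(9.20, abs=0.005)
    assert franz_balance.loc[("MCF1", 2), "receptor_pct"] == pytest.approx(0.001, abs=5e-4)
    assert franz_balance.loc[("MCF2", 2), "donor_pct"] == pytest.approx(75.8, abs=0.05)


def test_absorption_fraction_from_receptor_percents(franz_balance):
    """Across-MCF mean receptor percent gives the scenario absorption inputs."""
    assert F.absorption_fraction(franz_balance, 2) == pytest.approx(0.00197, abs=5e-5)
    assert F.absorption_fraction(franz_balance, 24) == pytest.approx(0.00374, abs=5e-5)


def test_reservoir_trend_identical_groups_is_null():
    res = F.reservoir_trend({2.0: [1.0, 1.0], 4.0: [1.0, 1.0], 24.0: [1.0, 1.0]})
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_reservoir_trend_detects_increasing_reservoir():
    runs, matrix = simulate_franz(FranzSimParams(measurement_cv=0.0), seed=3)
    sel = runs[runs["mcf_id"] == "MCF2"]
    groups = {t: (g["skin_ug"] / g["area_cm2"]).tolist() for t, g in sel.groupby("time_h")}
    res = F.reservoir_trend(groups)
    assert res.extra["increasing"] is True
    assert res.statistic >= 0


def test_reservoir_trend_fully_separated_groups_maximal_h():
    # three fully rank-separated groups of 4: H from direct rank arithmetic
    groups = {2.0: [1, 2, 3, 4], 4.0: [10, 11, 12, 13], 24.0: [20, 21, 22, 23]}
    res = F.reservoir_trend({k: list(map(float, v)) for k, v in groups.items()})
    n = 12
    mean_ranks = [2.5, 6.5, 10.5]
    h_direct = 12.0 / (n * (n + 1)) * sum(4 * (r - 6.5) ** 2 for r in mean_ranks)
    assert res.statistic == pytest.approx(h_direct)
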