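"""Study-level model object tying the pipeline together.

:class:`LeadExposureModel` is constructed from study data (worker table,
tidy skin doses, optionally diffusion-cell data) and a scenario; its
:meth:`~LeadExposureModel.fit` estimates the study mean skin dose, runs
the three-route uptake model through the adult-lead-model slope-factor
conversion, and computes the study's nonparametric diagnostics
(blood-dose Spearman correlations per hand, Kruskal-Wallis + Dunn site
comparison, skin-reservoir time trend).  The returned
:class:`LeadExposureResults` carries the estimates and renders a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import exposure, franz, nonparametric, wipes
from .exposure import ExposureScenario, RouteAssessment
from .nonparametric import TestResult

__all__ = ["LeadExposureModel", "LeadExposureResults"]


class LeadExposureModel:
    """Multi-route lead exposure model for one worker cohort.

    Parameters
    ----------
    doses : tidy DataFrame
        Columns worker_id, hand, site, dose_ug_cm2 (reference-corrected).
    workers : DataFrame, optional
        Columns worker_id, blood_pb_ugdl (LOD-substituted), glove_use.
        Needed for the blood-dose correlations and glove subsets.
    scenario : ExposureScenario, optional
        Model parameters; its ``avg_skin_dose`` is replaced by the mean
        estimated from ``doses`` at fit time.
    franz_runs, mcf_matrix : DataFrames, optional
        Per-cell diffusion runs and t=0 matrix samples; reduced at fit
        time to a mass balance.
    franz_balance : DataFrame, optional
        An already-reduced mass balance (e.g. from published group
        means); used directly when per-cell runs are absent.
    """

    def __init__(
        self,
        doses: pd.DataFrame,
        workers: pd.DataFrame | None = None,
        scenario: ExposureScenario | None = None,
        franz_runs: pd.DataFrame | None = None,
        mcf_matrix: pd.DataFrame | None = None,
        franz_balance: pd.DataFrame | None = None,
    ):
        if doses is None or doses.empty:
            raise ValueError("need a non-empty dose table")
        self.doses = doses
        self.workers = workers
        self.scenario = scenario or ExposureScenario()
        self.franz_runs = franz_runs
        self.mcf_matrix = mcf_matrix
        self.franz_balance = franz_balance

    @classmethod
    def from_study_tables(cls, scenario: ExposureScenario | None = None) -> "LeadExposureModel":
        """Build the model from the packaged study tables."""
        from . import datasets

        amounts = datasets.load_franz_amounts()
        return cls(
            doses=datasets.load_skin_doses(),
            workers=datasets.load_workers(),
            scenario=scenario or datasets.default_scenario(),
            franz_balance=franz.balance_from_means(amounts),
        )

    @classmethod
    def from_bundle(cls, bundle) -> "LeadExposureModel":
        """Build the model from a loaded :class:`~pbroutes.io.StudyBundle`."""
        scenario = bundle.scenario
        if bundle.air is not None:
            scenario = replace(
                scenario, air_concentration=float(bundle.air["air_ug_m3"].mean())
            )
        return cls(
            doses=bundle.doses,
            workers=bundle.workers,
            scenario=scenario,
            franz_runs=bundle.franz_runs,
            mcf_matrix=bundle.mcf_matrix,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, exclude_workers=None) -> "LeadExposureResults":
        """Estimate the mean dose, route contributions and diagnostics.

        ``exclude_workers`` drops whole workers before estimating the
        mean skin dose (the glove-only sensitivity excludes the workers
        who wore no gloves); diagnostics always use the full cohort.
        """
        mean_dose = wipes.mean_skin_dose(self.doses, exclude=exclude_workers)
        scenario = self.scenario.with_skin_dose(mean_dose)
        assessment = exposure.assess(scenario)

        correlations = self._correlations()
        site_comparison = self._site_comparison()

        balance = self.franz_balance
        if balance is None and self.franz_runs is not None:
            balance = franz.reduce_cells(self.franz_runs, self.mcf_matrix)
        absorption = mean_rates = None
        reservoir = None
        if balance is not None:
            times = balance.index.get_level_values("time_h").unique()
            absorption = {
                float(t): franz.absorption_fraction(balance, t) for t in sorted(times)
            }
            mean_rates = {
                float(t): franz.mean_over_mcfs(
                    balance.xs(t, level="time_h")["rate_ng_cm2_h"].to_numpy()
                )
                for t in sorted(times)
            }
        if self.franz_runs is not None:
            per_cell = {
                float(t): (grp["skin_ug"] / grp["area_cm2"]).tolist()
                for t, grp in self.franz_runs.groupby("time_h")
            }
            if len(per_cell) >= 2 and all(len(v) >= 2 for v in per_cell.values()):
                reservoir = franz.reservoir_trend(per_cell)

        return LeadExposureResults(
            model=self,
            scenario=scenario,
            mean_skin_dose=mean_dose,
            excluded_workers=tuple(str(w) for w in (exclude_workers or ())),
            assessment=assessment,
            correlations=correlations,
            site_comparison=site_comparison,
            franz_balance=balance,
            absorption_fractions=absorption,
            mean_diffusion_rates=mean_rates,
            reservoir_trend=reservoir,
        )

    def fit_glove_only(self) -> "LeadExposureResults":
        """Sensitivity fit excluding workers who did not wear gloves."""
        if self.workers is None or "glove_use" not in self.workers:
            raise ValueError("glove sensitivity needs a worker table with glove_use")
        bare = self.workers.loc[~self.workers["glove_use"].astype(bool), "worker_id"]
        return self.fit(exclude_workers=bare.tolist())

    # -- diagnostics -------------------------------------------------------

    def _correlations(self) -> dict[str, TestResult] | None:
        if self.workers is None or "blood_pb_ugdl" not in self.workers:
            return None
        sums = wipes.hand_sums(self.doses)
        blood = self.workers.set_index("worker_id")["blood_pb_ugdl"].reindex(sums.index)
        if blood.isna().any() or len(blood) < 3:
            return None
        return {
            hand: nonparametric.spearman(blood.to_numpy(), sums[hand].to_numpy())
            for hand in ("left", "right")
        }

    def _site_comparison(self) -> TestResult | None:
        groups, labels = [], []
        for hand in ("left", "right"):
            for site in ("palm", "wrist", "index"):
                sel = self.doses[
                    (self.doses["hand"] == hand) & (self.doses["site"] == site)
                ]["dose_ug_cm2"]
                if len(sel) < 2:
                    return None
                groups.append(sel.to_numpy(dtype=float))
                labels.append(f"{hand}:{site}")
        return nonparametric.dunns_test(groups, labels=labels, adjust="bonferroni")


@dataclass
class LeadExposureResults:
    """Fitted estimates, route contributions and diagnostics."""

    model: LeadExposureModel
    scenario: ExposureScenario
    mean_skin_dose: float                   # ug cm-2
    excluded_workers: tuple[str, ...]
    assessment: RouteAssessment
    correlations: dict[str, TestResult] | None
    site_comparison: TestResult | None
    franz_balance: pd.DataFrame | None
    absorption_fractions: dict[float, float] | None
    mean_diffusion_rates: dict[float, float] | None
    reservoir_trend: TestResult | None

    # convenience passthroughs for report rendering
    @property
    def doses(self) -> pd.DataFrame:
        return self.model.doses

    @property
    def workers(self) -> pd.DataFrame | None:
        return self.model.workers

    @property
    def routes(self) -> pd.DataFrame:
        """Route table: uptake (ug day-1) and blood Pb (ug dl-1) per route."""
        return pd.DataFrame(
            {
                "uptake_ug_day": {r.route: r.uptake for r in self.assessment.routes},
                "blood_pb_ugdl": {r.route: r.blood_pb for r in self.assessment.routes},
            }
        )

    @property
    def ranking(self) -> tuple[str, ...]:
        return self.assessment.ranking

    def to_dict(self) -> dict:
        """All unrounded headline quantities, JSON-serialisable."""
        out = {
            "mean_skin_dose_ug_cm2": self.mean_skin_dose,
            "excluded_workers": list(self.excluded_workers),
            "routes": {
                r.route: {"uptake_ug_day": r.uptake, "blood_pb_ugdl": r.blood_pb}
                for r in self.assessment.routes
            },
            "total_blood_pb_ugdl": {
                "with_dermal_2h": self.assessment.total_blood_2h,
                "with_dermal_24h": self.assessment.total_blood_24h,
            },
            "ranking": list(self.ranking),
        }
        if self.correlations:
            out["spearman"] = {
                hand: {"rho": t.statistic, "p": t.p_value, "method": t.method}
                for hand, t in self.correlations.items()
            }
        if self.site_comparison is not None:
            out["site_comparison"] = {
                "H": self.site_comparison.statistic,
                "p": self.site_comparison.p_value,
                "pairs": {
                    f"{a}|{b}": d["p_adjusted"]
                    for (a, b), d in self.site_comparison.comparisons.items()
                },
            }
        if self.absorption_fractions:
            out["absorption_fraction_pct"] = dict(self.absorption_fractions)
        if self.mean_diffusion_rates:
            out["mean_diffusion_rate_ng_cm2_h"] = dict(self.mean_diffusion_rates)
        if self.reservoir_trend is not None:
            out["reservoir_trend"] = {
                "H": self.reservoir_trend.statistic,
                "p": self.reservoir_trend.p_value,
                "increasing": bool(self.reservoir_trend.extra.get("increasing")),
            }
        return out

    def summary(self) -> str:
        """Human-readable summary in the style of the study's route table."""
        s = self.scenario
        lines = [
            "Multi-route lead exposure assessment",
            "=" * 68,
            f"Workers included: {'all' if not self.excluded_workers else 'all except ' + ', '.join(self.excluded_workers)}",
            f"Mean 2-h skin dose D: {self.mean_skin_dose:.4g} ug cm-2",
            f"Air Pb C_air: {s.air_concentration:.3g} ug m-3   "
            f"BKSF: {s.bksf}   workdays/365: {s.annualization:.3f}",
            "-" * 68,
            f"{'route':<14}{'parameters':<30}{'uptake':>10}{'blood Pb':>12}",
            f"{'':<14}{'':<30}{'ug/day':>10}{'ug/dl':>12}",
            "-" * 68,
        ]
        rows = [
            ("dermal_2h", f"A={s.hand_area:g} cm2, f={s.skin_absorption_2h:g}"),
            ("dermal_24h", f"A={s.hand_area:g} cm2, f={s.skin_absorption_24h:g}"),
            (
                "ingestion",
                f"A={s.contact_area:g} cm2, {s.contact_frequency:g}/h x {s.shift_hours:g} h",
            ),
            ("inhalation", f"C={s.air_concentration:g} ug/m3, V={s.inhaled_volume:g} m3"),
        ]
        for route, params in rows:
            r = self.assessment[route]
            lines.append(f"{route:<14}{params:<30}{r.uptake:>10.1f}{r.blood_pb:>12.2f}")
        lines += [
            "-" * 68,
            f"Route ranking by blood-Pb contribution: {' > '.join(self.ranking)}",
            f"Total blood-Pb contribution: {self.assessment.total_blood_2h:.2f} (dermal 2 h) "
            f"/ {self.assessment.total_blood_24h:.2f} (dermal 24 h) ug dl-1",
        ]
        if self.correlations:
            for hand, t in self.correlations.items():
                lines.append(
                    f"Spearman blood vs {hand}-hand dose sum: rho = {t.statistic:.3f}, "
                    f"p = {t.p_value:.4f} ({t.method})"
                )
        if self.mean_diffusion_rates:
            rates = ", ".join(
                f"{t:g} h: {v:.2f}" for t, v in self.mean_diffusion_rates.items()
            )
            lines.append(f"Mean diffusion rate across MCFs (ng cm-2 h-1): {rates}")
        return "\n".join(lines)
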