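"""Model/Results front door for cohort demography analyses.

``CohortDemography`` wraps a set of individually followed females
(possibly several cohorts), exposes their life tables, and ``fit()``
returns a ``DemographyResults`` carrying the population-increase
parameters with bootstrap uncertainty, significance letters and
survival-curve comparisons, statsmodels-style::

    model = CohortDemography.from_csv("females.csv", "exposures.csv")
    res = model.fit(mode="ratio", n_replicates=1000, seed=7)
    print(res.summary())
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthError, PopParams, population_parameters, round_half_up
from .inference import (
    BootstrapResult,
    LogRankResult,
    ci_letters,
    logrank_test,
    stratified_bootstrap,
)
from .records import (
    ALL_FEMALE,
    CohortError,
    IndividualRecord,
    LifeTable,
    build_cohort_schedule,
    compute_life_table,
    median_survival_age,
    offspring_sex_ratio,
)

__all__ = ["CohortDemography", "DemographyResults"]


class CohortDemography:
    """Cohort life-table demography model over individual female records."""

    def __init__(self, records: Sequence[IndividualRecord]):
        if not records:
            raise CohortError("empty cohort")
        by_cohort: dict[str, list[IndividualRecord]] = {}
        for rec in records:
            by_cohort.setdefault(rec.cohort_id, []).append(rec)
        self.records_by_cohort: dict[str, list[IndividualRecord]] = {
            k: by_cohort[k] for k in sorted(by_cohort)
        }
        self._life_tables: dict[str, LifeTable] = {}

    @classmethod
    def from_dataframes(
        cls, females: pd.DataFrame, exposures: pd.DataFrame
    ) -> "CohortDemography":
        from .io import records_from_dataframes

        return cls(records_from_dataframes(females, exposures))

    @classmethod
    def from_csv(cls, females_path, exposures_path) -> "CohortDemography":
        from .io import read_cohort_files

        return cls(read_cohort_files(females_path, exposures_path))

    @property
    def cohorts(self) -> list[str]:
        return list(self.records_by_cohort)

    def life_table(self, cohort_id: str) -> LifeTable:
        if cohort_id not in self._life_tables:
            sched = build_cohort_schedule(self.records_by_cohort[cohort_id])
            self._life_tables[cohort_id] = compute_life_table(sched)
        return self._life_tables[cohort_id]

    def median_survival(self, cohort_id: str) -> int | None:
        """l50: first age at which cohort survivorship is <= 50%."""
        return median_survival_age(self.life_table(cohort_id))

    def sex_ratio(self, cohort_id: str):
        """Lifetime daughters-per-son ratio for one cohort."""
        return offspring_sex_ratio(self.records_by_cohort[cohort_id])

    def fit(
        self,
        mode: str = "ratio",
        n_replicates: int = 1000,
        seed: int | None = None,
    ) -> "DemographyResults":
        """Estimate (R0, T, r, lambda) per cohort with bootstrap CIs."""
        params: dict[str, PopParams] = {}
        for cohort_id in self.cohorts:
            try:
                params[cohort_id] = population_parameters(
                    self.life_table(cohort_id), mode=mode, cohort_id=cohort_id
                )
            except GrowthError:
                pass  # no reproduction: bootstrap still reports R0 = 0
        bootstrap = stratified_bootstrap(
            self.records_by_cohort, n_replicates=n_replicates, seed=seed, mode=mode
        )
        return DemographyResults(
            model=self, mode=mode, seed=seed, params=params, bootstrap=bootstrap
        )


class DemographyResults:
    """Fitted demography: parameter estimates, uncertainty, comparisons."""

    def __init__(
        self,
        model: CohortDemography,
        mode: str,
        seed: int | None,
        params: Mapping[str, PopParams],
        bootstrap: Mapping[str, Mapping[str, BootstrapResult]],
    ):
        self.model = model
        self.mode = mode
        self.seed = seed
        self.params = dict(params)
        self.bootstrap = {k: dict(v) for k, v in bootstrap.items()}

    # -- comparisons --------------------------------------------------

    def letters(self, parameter: str) -> dict[str, str]:
        """Significance letters across cohorts from CI overlap."""
        cohorts = [
            c for c in self.model.cohorts
            if np.isfinite(self.bootstrap[c][parameter].ci_lo)
        ]
        if len(cohorts) < 2:
            return {c: "a" for c in cohorts}
        labels = ci_letters([self.bootstrap[c][parameter] for c in cohorts])
        return dict(zip(cohorts, labels))

    def compare_table(self) -> pd.DataFrame:
        """Long-format comparison: one row per cohort x parameter."""
        rows = []
        for parameter in ("R0", "r", "T", "lambda"):
            letters = self.letters(parameter)
            for cohort_id in self.model.cohorts:
                br = self.bootstrap[cohort_id][parameter]
                rows.append(
                    {
                        "parameter": parameter,
                        "cohort_id": cohort_id,
                        "estimate": br.point_estimate,
                        "se": br.se,
                        "ci_lo": br.ci_lo,
                        "ci_hi": br.ci_hi,
                        "letter": letters.get(cohort_id, ""),
                        "n_degenerate": br.n_degenerate,
                    }
                )
        return pd.DataFrame(rows)

    def logrank(self, cohort_a: str, cohort_b: str) -> LogRankResult:
        """Log-rank comparison of two cohorts' survival curves."""
        return logrank_test(
            self.model.records_by_cohort[cohort_a],
            self.model.records_by_cohort[cohort_b],
        )

    # -- reporting ----------------------------------------------------

    def summary(self, precision: int = 2) -> str:
        """Report table in the style of printed life-table studies."""
        p = precision
        lines = [
            f"Cohort demography ({self.mode} mode"
            + (f", seed={self.seed}" if self.seed is not None else "")
            + ")",
            "",
        ]
        header = (
            f"{'cohort':<16}{'n':>4}{'l50':>5} "
            f"{'R0':>22} {'r':>22} {'T':>22} {'lambda':>22}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for cohort_id in self.model.cohorts:
            n = len(self.model.records_by_cohort[cohort_id])
            l50 = self.model.median_survival(cohort_id)
            cells = []
            for parameter in ("R0", "r", "T", "lambda"):
                br = self.bootstrap[cohort_id][parameter]
                letter = self.letters(parameter).get(cohort_id, "")
                if np.isfinite(br.point_estimate):
                    cells.append(
                        f"{round_half_up(br.point_estimate, p):.{p}f}"
                        f"±{round_half_up(br.se, p):.{p}f}"
                        f" [{round_half_up(br.ci_lo, p):.{p}f}-"
                        f"{round_half_up(br.ci_hi, p):.{p}f}]{letter}"
                    )
                    cells[-1] = f"{cells[-1]:>22}"
                else:
                    cells.append(f"{'--':>22}")
            lines.append(
                f"{cohort_id:<16}{n:>4}{str(l50):>5} " + " ".join(cells)
            )
        pairs = list(itertools.combinations(self.model.cohorts, 2))
        if pairs:
            lines.append("")
            lines.append("Log-rank survival comparisons:")
            for a, b in pairs:
                res = self.logrank(a, b)
                lines.append(
                    f"  {a} vs {b}: chi2={round_half_up(res.chi2, 2):.2f}, "
                    f"df={res.df}, p={round_half_up(res.p, 3):.3f}"
                )
        return "\n".join(lines)

    # -- plots --------------------------------------------------------

    def plot_survival(self, ax=None):
        """Step plot of lx per cohort."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cohort_id in self.model.cohorts:
            lt = self.model.life_table(cohort_id)
            ages = np.append(lt.ages, lt.ages[-1] + 1)
            lx = np.append(lt.lx, 0.0)
            ax.step(ages, lx, where="post", label=cohort_id)
        ax.set_xlabel("age (days)")
        ax.set_ylabel("$l_x$")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax

    def plot_fecundity(self, ax=None):
        """Daily daughters per living female (mx) per cohort."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cohort_id in self.model.cohorts:
            lt = self.model.life_table(cohort_id)
            ax.plot(lt.ages, lt.mx, marker="o", ms=3, lw=1, label=cohort_id)
        ax.set_xlabel("maternal age (days)")
        ax.set_ylabel("$m_x$ (daughters/female/day)")
        ax.legend()
        return ax
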