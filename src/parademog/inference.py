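"""Resampling inference for population parameters and survival comparison.

Uncertainty in (R0, T, r, lambda) is quantified by a stratified
bootstrap: females are resampled with replacement within their cohort
(the stratum), each replicate's life table is rebuilt from scratch and
the parameters recomputed, and the replicate distribution yields the SE
(sample standard deviation) and a 95% percentile confidence interval.
Resampling whole females with their exposure histories attached
preserves the within-female correlation between longevity and fecundity.

Replicates in which no daughters were drawn at all have R0 = 0 and no
finite r, T or lambda; such replicates are retained for R0, dropped for
the other three parameters, and counted in ``n_degenerate``.

Survival curves are compared with the standard two-sample log-rank test
(all females followed to death, so there is no censoring), and groups
are assigned compact significance letters from pairwise overlap of their
confidence intervals, the convention used in rearing-quality report
tables: groups sharing a letter do not differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _ll_logrank

from .growth import GrowthError, _lotka_root
from .records import CohortError, IndividualRecord

__all__ = [
    "BootstrapResult",
    "LogRankResult",
    "stratified_bootstrap",
    "bootstrap_cohort",
    "ci_letters",
    "logrank_test",
]

PARAMETERS = ("R0", "T", "r", "lambda")


@dataclass
class BootstrapResult:
    """Bootstrap summary for one parameter of one cohort."""

    parameter: str
    point_estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    n_replicates: int
    n_degenerate: int
    seed: int | None
    replicates: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "estimate": self.point_estimate,
            "se": self.se,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "n_replicates": self.n_replicates,
            "n_degenerate": self.n_degenerate,
        }


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def _cohort_arrays(records: Sequence[IndividualRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-female death ages and (n, xmax) daughters-by-maternal-age matrix."""
    deaths = np.array([rec.age_at_death for rec in records], dtype=np.int64)
    xmax = int(deaths.max())
    D = np.zeros((len(records), xmax), dtype=np.float64)
    for i, rec in enumerate(records):
        for e in rec.exposures:
            D[i, e.maternal_age] += e.daughters
    return deaths, D


def _params_from_counts(
    n_alive: np.ndarray, daughters: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ratio-mode (R0, T, r, lambda) for stacked replicates.

    n_alive and daughters have shape (R, xmax); rows with R0 = 0 get NaN
    for T, r and lambda.
    """
    ages = np.arange(n_alive.shape[1], dtype=np.float64)
    lx = n_alive / float(n)
    mx = np.where(n_alive > 0, daughters / np.maximum(n_alive, 1), 0.0)
    phi = lx * mx
    R0 = phi.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(R0 > 0, (phi * ages).sum(axis=1) / np.where(R0 > 0, R0, 1.0), np.nan)
        r = np.where((R0 > 0) & (T > 0), np.log(np.where(R0 > 0, R0, 1.0)) / T, np.nan)
    lam = np.exp(r)
    T = np.where(R0 > 0, T, np.nan)
    return R0, T, r, lam


def bootstrap_cohort(
    records: Sequence[IndividualRecord],
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: str = "ratio",
) -> dict[str, BootstrapResult]:
    """Bootstrap (R0, T, r, lambda) for a single cohort of females.

    Each replicate draws n females with replacement and recomputes the
    four parameters from the rebuilt life table. ratio mode is fully
    vectorised; lotka mode solves the Euler–Lotka root per replicate.
    """
    if len(records) < 2:
        raise CohortError("bootstrap needs at least 2 females per cohort")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None

    deaths, D = _cohort_arrays(records)
    n = deaths.size
    ages = np.arange(int(deaths.max()))

    # point estimates on the original sample
    n_alive0 = (deaths[:, None] > ages).sum(axis=0)[None, :].astype(float)
    daughters0 = D.sum(axis=0)[None, :]
    R0_0, T_0, r_0, lam_0 = _params_from_counts(n_alive0, daughters0, n)
    point = {"R0": R0_0[0], "T": T_0[0], "r": r_0[0], "lambda": lam_0[0]}

    idx = rng.integers(0, n, size=(n_replicates, n))
    d = deaths[idx]
    n_alive = (d[:, :, None] > ages).sum(axis=1).astype(float)
    daughters = D[idx].sum(axis=1)
    R0, T, r, lam = _params_from_counts(n_alive, daughters, n)

    if mode == "lotka":
        phi = (n_alive / n) * np.where(n_alive > 0, daughters / np.maximum(n_alive, 1), 0.0)
        full_ages = np.arange(n_alive.shape[1])
        for i in range(n_replicates):
            if not R0[i] > 0:
                continue
            try:
                r[i] = _lotka_root(full_ages, phi[i])
                T[i] = math.log(R0[i]) / r[i] if r[i] != 0 else T[i]
                lam[i] = math.exp(r[i])
            except GrowthError:
                r[i] = T[i] = lam[i] = np.nan
        # recompute the point estimate in the same mode
        try:
            r0 = _lotka_root(full_ages, (n_alive0[0] / n) * np.where(
                n_alive0[0] > 0, daughters0[0] / np.maximum(n_alive0[0], 1), 0.0))
            point["r"] = r0
            point["T"] = math.log(point["R0"]) / r0 if r0 != 0 else point["T"]
            point["lambda"] = math.exp(r0)
        except GrowthError:
            point["r"] = point["T"] = point["lambda"] = np.nan
    elif mode != "ratio":
        raise ValueError(f"unknown mode {mode!r}")

    out: dict[str, BootstrapResult] = {}
    for name, reps in (("R0", R0), ("T", T), ("r", r), ("lambda", lam)):
        kept = reps[np.isfinite(reps)]
        n_degenerate = n_replicates - kept.size
        if kept.size == 0:
            out[name] = BootstrapResult(
                parameter=name, point_estimate=point[name], se=math.nan,
                ci_lo=math.nan, ci_hi=math.nan, n_replicates=n_replicates,
                n_degenerate=n_degenerate, seed=seed_repr, replicates=kept,
            )
            continue
        if kept.size <= 1 or np.ptp(kept) == 0.0:
            se = 0.0  # constant replicates: SE exactly 0, no mean round-off
        else:
            se = float(np.std(kept, ddof=1))
        lo, hi = np.percentile(kept, [2.5, 97.5])
        out[name] = BootstrapResult(
            parameter=name,
            point_estimate=float(point[name]),
            se=se,
            ci_lo=float(lo),
            ci_hi=float(hi),
            n_replicates=n_replicates,
            n_degenerate=n_degenerate,
            seed=seed_repr,
            replicates=kept,
        )
    return out


def stratified_bootstrap(
    records_by_cohort: Mapping[str, Sequence[IndividualRecord]],
    n_replicates: int = 1000,
    seed: int | None = None,
    mode: str = "ratio",
) -> dict[str, dict[str, BootstrapResult]]:
    """Bootstrap every cohort independently (cohort = stratum).

    Cohorts are processed in sorted label order from a single seeded
    generator, so results are reproducible regardless of mapping order.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, BootstrapResult]] = {}
    for cohort_id in sorted(records_by_cohort):
        res = bootstrap_cohort(
            records_by_cohort[cohort_id], n_replicates=n_replicates, seed=rng, mode=mode
        )
        for br in res.values():
            br.seed = seed
        out[cohort_id] = res
    return out


def _maximal_cliques_of_intervals(intervals: Sequence[tuple[float, float]]) -> list[frozenset]:
    """Maximal cliques of the interval-overlap graph (closed intervals)."""
    n = len(intervals)
    cliques = []
    for i in range(n):
        lo = intervals[i][0]
        members = frozenset(
            j for j in range(n) if intervals[j][0] <= lo <= intervals[j][1]
        )
        cliques.append(members)
    # drop cliques contained in another
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    uniq: list[frozenset] = []
    for c in maximal:
        if c not in uniq:
            uniq.append(c)
    return uniq


def ci_letters(
    groups: Sequence[BootstrapResult] | Sequence[tuple[float, float, float]],
) -> list[str]:
    """Compact letter display from confidence-interval overlap.

    Input per group: a BootstrapResult or a tuple (estimate, ci_lo,
    ci_hi). Groups whose intervals overlap share at least one letter;
    disjoint groups share none. Letters are assigned to the maximal
    overlap cliques in descending order of their largest member
    estimate, so the group with the highest point estimate always
    carries 'a'. Output is aligned with the input order and invariant
    (up to this canonical labelling) under permutation of the input.
    """
    items = []
    for g in groups:
        if isinstance(g, BootstrapResult):
            items.append((g.point_estimate, g.ci_lo, g.ci_hi))
        else:
            est, lo, hi = g
            items.append((float(est), float(lo), float(hi)))
    if len(items) < 2:
        raise ValueError("need at least 2 groups to assign letters")
    if any(not (lo <= hi) for _, lo, hi in items):
        raise ValueError("each group needs a valid ci_lo <= ci_hi")
    intervals = [(lo, hi) for _, lo, hi in items]
    cliques = _maximal_cliques_of_intervals(intervals)
    order = sorted(
        range(len(cliques)),
        key=lambda k: (
            -max(items[j][0] for j in cliques[k]),
            -min(items[j][0] for j in cliques[k]),
            sorted(cliques[k]),
        ),
    )
    letter_of_clique = {}
    for rank, k in enumerate(order):
        letter_of_clique[k] = chr(ord("a") + rank)
    labels = []
    for j in range(len(items)):
        letters = sorted(
            letter_of_clique[k] for k, c in enumerate(cliques) if j in c
        )
        labels.append("".join(letters))
    return labels


def logrank_test(
    group_a: Sequence[IndividualRecord], group_b: Sequence[IndividualRecord]
) -> LogRankResult:
    """Two-sample log-rank comparison of female survival curves.

    All females are followed to death (no censoring); the statistic is
    the usual (O - E)^2 / V chi-square with 1 df over pooled risk sets.
    """
    if not group_a or not group_b:
        raise CohortError("both groups must be non-empty")
    dur_a = [rec.age_at_death for rec in group_a]
    dur_b = [rec.age_at_death for rec in group_b]
    res = _ll_logrank(dur_a, dur_b)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if chi2 < 1e-12:
        chi2, p = 0.0, 1.0
    return LogRankResult(chi2=chi2, df=1, p=p)
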