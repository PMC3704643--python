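"""Scenario replication and sensitivity statistics.

Three sensitivity axes are supported, mirroring the standard design for
larval-dispersal studies: pelagic larval duration (tested by ordinary
least-squares regression of each response on PLD in days), diel vertical
migration on/off (two-sample pooled-variance t test), and spawning month
(one-way ANOVA). Replicates of different scenarios share seeds (replicate r
uses base_seed + r) so scenario contrasts are paired through common random
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .connectivity import (assign_settlement, connectance, connectivity_matrix,
                           dispersal_distances)
from .graphs import build_graph, n_clusters, strong_clusters, weak_clusters
from .grids import GridSpec, MPASite, ValidationError, VelocityField
from .shelf import export_summary
from .tracker import SimulationConfig, run_simulation

RESPONSES = ("median_dispersal_km", "p75_dispersal_km", "connectance",
             "n_strong_clusters", "n_weak_clusters", "frac_on_shelf",
             "frac_shelf_unseeded")


@dataclass
class RegressionFit:
    slope: float
    stderr: float
    adj_r2: float
    pvalue: float
    intercept: float
    n: int


@dataclass
class ScenarioPlan:
    """The grid of scenarios to run.

    ``pld_days`` defaults to integer days 20..40; months are calendar month
    numbers whose 1st is the spawn start.
    """

    pld_days: Sequence[float] = tuple(range(20, 41))
    vertical_migration: Sequence[bool] = (False,)
    spawn_months: Sequence[int] = (8,)
    n_replicates: int = 1
    base_seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValidationError("plan needs at least 1 replicate")

    def cells(self):
        for pld in self.pld_days:
            for vm in self.vertical_migration:
                for month in self.spawn_months:
                    for rep in range(self.n_replicates):
                        yield pld, vm, month, rep


def scenario_responses(traj, grid: GridSpec, mpas: Sequence[MPASite]) -> dict:
    """The seven response variables of one finished run."""
    counts = assign_settlement(traj, mpas)
    released = np.array([np.sum(traj.source_mpa == m.id)
                         for m in sorted(mpas, key=lambda m: m.id)], dtype=float)
    C = connectivity_matrix(counts, released, [m.id for m in sorted(mpas, key=lambda m: m.id)])
    g = build_graph(C)
    dist = dispersal_distances(traj)
    exp = export_summary(traj, grid, mpas)
    d = dist["per_particle_km"]
    return {
        "median_dispersal_km": float(np.median(d)) if len(d) else np.nan,
        "p75_dispersal_km": float(np.percentile(d, 75)) if len(d) else np.nan,
        "connectance": connectance(C),
        "n_strong_clusters": n_clusters(strong_clusters(g)),
        "n_weak_clusters": n_clusters(weak_clusters(g)),
        "frac_on_shelf": exp.frac_on_shelf,
        "frac_shelf_unseeded": exp.frac_shelf_unseeded,
    }


def run_scenarios(field: VelocityField, grid: GridSpec, mpas: Sequence[MPASite],
                  base_config: SimulationConfig, plan: ScenarioPlan) -> pd.DataFrame:
    """Run the full pipeline for every cell of the plan; tidy result table.

    One row per (pld, vertical_migration, spawn_month, replicate);
    deterministic for a given ``plan.base_seed``.
    """
    year = np.datetime_as_string(field.times[0], unit="Y")
    rows = []
    for pld, vm, month, rep in plan.cells():
        cfg = replace(base_config, pld_days=float(pld), vertical_migration=vm,
                      spawn_start_date=f"{year}-{month:02d}-01",
                      seed=plan.base_seed + rep)
        traj = run_simulation(field, grid, mpas, cfg)
        resp = scenario_responses(traj, grid, mpas)
        rows.append({"pld_days": pld, "vertical_migration": vm,
                     "spawn_month": month, "replicate": rep,
                     "seed": cfg.seed, **resp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def pld_regression(table: pd.DataFrame, response: str) -> RegressionFit:
    """OLS of a response on PLD (days): slope per one-day PLD increase.

    Two-sided p from the t distribution with n-2 degrees of freedom.
    """
    if response not in table.columns:
        raise ValidationError(f"unknown response {response!r}")
    sub = table.dropna(subset=["pld_days", response])
    if sub["pld_days"].nunique() < 3:
        raise ValidationError("need at least 3 distinct PLD values")
    X = sm.add_constant(sub["pld_days"].to_numpy(dtype=float))
    fit = sm.OLS(sub[response].to_numpy(dtype=float), X).fit()
    return RegressionFit(slope=float(fit.params[1]), stderr=float(fit.bse[1]),
                         adj_r2=float(fit.rsquared_adj), pvalue=float(fit.pvalues[1]),
                         intercept=float(fit.params[0]), n=int(fit.nobs))


def scenario_ttest(group_a, group_b):
    """Two-sample pooled-variance (Student's) t test; returns (t, p).

    Degenerate zero-variance groups with equal means give (0, 1) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 replicates per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def scenario_anova(*groups):
    """One-way fixed-effects ANOVA across >= 2 groups; returns (F, p)."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValidationError("each group needs at least 2 replicates")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    f, p = scipy.stats.f_oneway(*arrs)
    return float(f), float(p)


def sensitivity_report(table: pd.DataFrame) -> pd.DataFrame:
    """Tables-style report: per response, PLD regression and/or group tests.

    Emits one row per (axis, response) with estimate, SE/sd and p-value for
    every axis with enough variation in the table.
    """
    rows = []
    if table["pld_days"].nunique() >= 3:
        base = table[(~table["vertical_migration"])
                     & (table["spawn_month"] == table["spawn_month"].iloc[0])]
        for r in RESPONSES:
            fit = pld_regression(base, r)
            rows.append({"axis": "pld", "response": r, "estimate": fit.slope,
                         "se_or_sd": fit.stderr, "fit": fit.adj_r2, "p": fit.pvalue})
    if table["vertical_migration"].nunique() == 2:
        pld0 = table["pld_days"].iloc[0]
        sub = table[table["pld_days"] == pld0]
        off = sub[~sub["vertical_migration"]]
        on = sub[sub["vertical_migration"]]
        if len(off) >= 2 and len(on) >= 2:
            for r in RESPONSES:
                t, p = scenario_ttest(off[r], on[r])
                rows.append({"axis": "vertical_migration", "response": r,
                             "estimate": on[r].mean() - off[r].mean(),
                             "se_or_sd": off[r].std(ddof=1), "fit": t, "p": p})
    months = sorted(table["spawn_month"].unique())
    if len(months) >= 2:
        sub = table[~table["vertical_migration"]]
        pld0 = sub["pld_days"].iloc[0]
        sub = sub[sub["pld_days"] == pld0]
        groups = [sub[sub["spawn_month"] == m] for m in months]
        if all(len(g) >= 2 for g in groups):
            for r in RESPONSES:
                f, p = scenario_anova(*[g[r] for g in groups])
                rows.append({"axis": "spawn_month", "response": r,
                             "estimate": np.nan, "se_or_sd": np.nan,
                             "fit": f, "p": p})
    return pd.DataFrame(rows)
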