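"""Monte-Carlo operating characteristics of the concordance tests.

For a design cell (rate, margin, compound correlation, target power) the
scenario runner solves the component correlations, computes the required
sample size, simulates many trials under the null and under the design
alternative with the latent-Gaussian generator, applies the Z-test to each,
and reports the empirical type-I error and power with binomial Monte-Carlo
standard errors.  ``reproduce_table`` sweeps the full 48-cell grid used in
the numerical studies for either objective.

Simulation is vectorised across replicate trials in memory-bounded chunks,
so a full table at 2,000 replicates per cell runs in minutes on one core.
Seeding is hierarchical: each (cell, hypothesis) stream gets its own
``numpy.random.SeedSequence(seed, spawn_key=(objective, cell_index,
condition))``, so results are reproducible cell by cell and independent of
execution order.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .correlations import solve_components_obj1, solve_components_obj2
from .design import (
    Design1Spec,
    Design2Spec,
    samplesize_objective1,
    samplesize_objective2,
)
from .simulate import IndicatorLayout, LatentModel, assemble_layout

__all__ = ["Scenario", "ScenarioResult", "run_scenario", "reproduce_table"]

RATES = (0.3, 0.5, 0.7)
DELTAS = (0.05, 0.1)
RHOS = (0.1, 0.3, 0.5, 0.7)
POWERS = (0.8, 0.9)

# replicate chunk size chosen so one latent draw block stays ~tens of MB
_MAX_BLOCK = 8_000_000


@dataclass(frozen=True)
class Scenario:
    """One Monte-Carlo design cell."""

    objective: int
    rate: float  # pr (objective 1) or px (objective 2)
    delta: float  # delta1 or delta2
    rho_target: float
    power_target: float
    m: int | None = None  # defaults: 10 (obj 1), 5 per group (obj 2)
    alpha: float = 0.05
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in (1, 2):
            raise ValueError(f"objective must be 1 or 2, got {self.objective}")
        if self.reps < 100:
            raise ValueError(f"need reps >= 100, got {self.reps}")

    @property
    def m_resolved(self) -> int:
        return self.m if self.m is not None else (10 if self.objective == 1 else 5)


@dataclass(frozen=True)
class ScenarioResult:
    """Empirical operating characteristics of one design cell."""

    scenario: Scenario
    n: int
    alpha_hat: float
    power_hat: float
    mc_se_alpha: float
    mc_se_power: float
    degenerate_null: int
    degenerate_alt: int


def _reject_fraction_obj1(
    model: LatentModel, n: int, delta1: float, alpha: float, reps: int,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Fraction of simulated trials with Z1 > z_{1-alpha}; degenerate count."""
    npair = model.layout.n_pair_indicators
    crit = norm.isf(alpha)
    d = model.layout.dimension
    chunk = max(1, min(reps, _MAX_BLOCK // (n * d)))
    rej = 0
    degenerate = 0
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        x = model.sample(k * n, rng).reshape(k, n, d)
        r_i = x[:, :, :npair].mean(axis=2)
        s_i = x[:, :, npair:].mean(axis=2)
        diff = s_i - r_i + delta1
        msq = (diff**2).mean(axis=1)
        ok = msq > 0
        degenerate += int((~ok).sum())
        z1 = np.full(k, -np.inf)
        z1[ok] = math.sqrt(n) * diff.mean(axis=1)[ok] / np.sqrt(msq[ok])
        rej += int((z1 > crit).sum())
        done += k
    return rej / reps, degenerate


def _reject_fraction_obj2(
    model: LatentModel, n: int, alpha: float, reps: int, rng: np.random.Generator
) -> tuple[float, int]:
    """Fraction of simulated trials with |Z2| > z_{1-alpha/2}."""
    m = model.layout.m
    crit = norm.isf(alpha / 2.0)
    d = model.layout.dimension
    chunk = max(1, min(reps, _MAX_BLOCK // (n * d)))
    rej = 0
    degenerate = 0
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        x = model.sample(k * n, rng).reshape(k, n, d)
        diff = x[:, :, :m].mean(axis=2) - x[:, :, m:].mean(axis=2)
        msq = (diff**2).mean(axis=1)
        ok = msq > 0
        degenerate += int((~ok).sum())
        z2 = np.zeros(k)
        z2[ok] = math.sqrt(n) * diff.mean(axis=1)[ok] / np.sqrt(msq[ok])
        rej += int((np.abs(z2) > crit).sum())
        done += k
    return rej / reps, degenerate


def _layouts(s: Scenario) -> tuple[int, IndicatorLayout, IndicatorLayout]:
    """Sample size plus null and alternative indicator layouts for a cell."""
    m = s.m_resolved
    if s.objective == 1:
        comps = solve_components_obj1(s.rho_target, m)
        spec = Design1Spec(
            pr=s.rate, delta1=s.delta, m=m, alpha=s.alpha,
            power=s.power_target, components=comps,
        )
        n = samplesize_objective1(spec)
        null = assemble_layout(1, m, (s.rate, s.rate - s.delta), comps)
        alt = assemble_layout(1, m, (s.rate, s.rate), comps)
    else:
        comps = solve_components_obj2(s.rho_target, m)
        spec = Design2Spec(
            px=s.rate, delta2=s.delta, m=m, alpha=s.alpha,
            power=s.power_target, components=comps,
        )
        n = samplesize_objective2(spec)
        null = assemble_layout(2, m, (s.rate, s.rate), comps)
        alt = assemble_layout(2, m, (s.rate, s.rate - s.delta), comps)
    return n, null, alt


def run_scenario(s: Scenario, cell_index: int = 0) -> ScenarioResult:
    """Empirical type-I error and power for one design cell.

    The null simulates at the boundary (ps = pr - delta1, or px = py at
    the rate px) with the same component correlations as the alternative;
    the alternative simulates at ps = pr (or px = py + delta2).
    """
    n, null_layout, alt_layout = _layouts(s)
    out: dict[str, tuple[float, int]] = {}
    for cond, layout in (("null", null_layout), ("alt", alt_layout)):
        ss = np.random.SeedSequence(
            s.seed, spawn_key=(s.objective, cell_index, 0 if cond == "null" else 1)
        )
        rng = np.random.default_rng(ss)
        model = LatentModel.from_layout(layout)
        if s.objective == 1:
            out[cond] = _reject_fraction_obj1(model, n, s.delta, s.alpha, s.reps, rng)
        else:
            out[cond] = _reject_fraction_obj2(model, n, s.alpha, s.reps, rng)
    for cond in ("null", "alt"):
        if out[cond][1] > 0.001 * s.reps:
            raise RuntimeError(
                f"{out[cond][1]} of {s.reps} replicates had degenerate "
                f"variance under the {cond} hypothesis"
            )
    a_hat, p_hat = out["null"][0], out["alt"][0]
    return ScenarioResult(
        scenario=s,
        n=n,
        alpha_hat=a_hat,
        power_hat=p_hat,
        mc_se_alpha=math.sqrt(a_hat * (1 - a_hat) / s.reps),
        mc_se_power=math.sqrt(p_hat * (1 - p_hat) / s.reps),
        degenerate_null=out["null"][1],
        degenerate_alt=out["alt"][1],
    )


def table_grid(objective: int) -> list[tuple[float, float, float, float]]:
    """The 48 (rate, delta, rho, power) cells of a numerical-study table."""
    return [
        (rate, delta, rho, power)
        for rate in RATES
        for delta in DELTAS
        for rho in RHOS
        for power in POWERS
    ]


def reproduce_table(
    table: int,
    reps: int = 10_000,
    seed: int = 0,
    cells: list[tuple[float, float, float, float]] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Recompute a numerical-study table (1: device-vs-panel, 2: senior-vs-junior).

    Returns one row per design cell with the required sample size and the
    empirical type-I error and power at ``reps`` replicates.  Failing cells
    are reported in an ``error`` column and do not stop the sweep.
    """
    if table not in (1, 2):
        raise ValueError(f"table must be 1 or 2, got {table}")
    grid = table_grid(table)
    if cells is not None:
        cells = [c for c in cells]
        unknown = [c for c in cells if tuple(c) not in grid]
        if unknown:
            raise ValueError(f"cells not in the table grid: {unknown}")
    rows = []
    rate_name = "pr" if table == 1 else "px"
    for idx, cell in enumerate(grid):
        if cells is not None and cell not in cells:
            continue
        rate, delta, rho, power = cell
        s = Scenario(
            objective=table, rate=rate, delta=delta, rho_target=rho,
            power_target=power, reps=reps, seed=seed,
        )
        row = {
            rate_name: rate, "delta": delta, "rho": rho,
            "power_target": power, "reps": reps, "error": "",
        }
        if progress:
            print(f"[table {table}] cell {idx + 1}/{len(grid)}: {cell}", file=sys.stderr)
        try:
            res = run_scenario(s, cell_index=idx)
            row.update(
                n=res.n, alpha_hat=res.alpha_hat, power_hat=res.power_hat,
                mc_se_alpha=res.mc_se_alpha, mc_se_power=res.mc_se_power,
            )
        except Exception as exc:  # keep sweeping, summarise at the end
            row.update(
                n=np.nan, alpha_hat=np.nan, power_hat=np.nan,
                mc_se_alpha=np.nan, mc_se_power=np.nan, error=str(exc),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    failures = df[df["error"] != ""]
    if progress and not failures.empty:
        print(f"[table {table}] {len(failures)} cell(s) failed", file=sys.stderr)
    return df
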