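"""Monte-Carlo power estimation over grids of two-level sample sizes.

Each replication simulates a fresh dataset, fits the candidate models and
records, per tested parameter, whether its p-value fell below alpha.  Power
is the proportion of significant results among converged replications, with
a binomial Monte-Carlo standard error attached.  Replications are keyed by
(grid cell, replication index) through numpy SeedSequence spawn keys, so a
run is reproducible and order-independent under any scheduler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm_inference import (
    FitResult,
    ModelStructure,
    fit,
    lrt_random_effect,
    wald_pvalue,
)
from .model_core import ScenarioSpec
from .simulate import simulate_dataset

__all__ = [
    "ALL_TARGETS",
    "FIXED_TARGETS",
    "ReplicationOutcome",
    "PowerResult",
    "PowerTable",
    "run_replication",
    "estimate_power",
    "power_curve",
    "mc_standard_error",
]

#: Wald-tested fixed effects and LRT-tested variance components
FIXED_TARGETS = ("gamma10", "gamma01", "gamma11")
VARIANCE_TARGETS = ("sigma0_sq", "sigma1_sq")
ALL_TARGETS = FIXED_TARGETS + VARIANCE_TARGETS


def mc_standard_error(power: float, n_converged: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n) of an estimated power."""
    if n_converged < 1:
        raise ValueError("n_converged must be >= 1")
    if not 0.0 <= power <= 1.0:
        raise ValueError("power must lie in [0, 1]")
    return float(np.sqrt(power * (1.0 - power) / n_converged))


@dataclass
class ReplicationOutcome:
    """Significance indicators (or None where excluded) for one replication."""

    significant: dict[str, bool | None]
    converged_full: bool
    converged_intercept_only: bool | None = None
    converged_no_random: bool | None = None


def _substream(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def run_replication(
    scenario: ScenarioSpec,
    n_level1: int,
    n_level2: int,
    rng: np.random.Generator,
    *,
    alpha: float = 0.05,
    targets: tuple[str, ...] = ALL_TARGETS,
    n_quadrature: int = 7,
) -> ReplicationOutcome:
    """Simulate one dataset, fit and test, return indicator(p < alpha).

    Fit failures never raise; they are recorded as convergence flags and the
    affected targets are marked None (excluded from power denominators).
    """
    unknown = set(targets) - set(ALL_TARGETS)
    if unknown:
        raise ValueError(f"unknown power targets: {sorted(unknown)}")
    need_lrt = any(t in targets for t in VARIANCE_TARGETS)

    data = simulate_dataset(scenario, n_level1, n_level2, rng)
    significant: dict[str, bool | None] = {t: None for t in targets}

    full_struct = ModelStructure(random_intercept=True, random_slope=True)
    try:
        full = fit(data, full_struct, n_quadrature=n_quadrature)
    except Exception:
        full = None
    conv_full = bool(full is not None and full.converged)

    if conv_full:
        for t in targets:
            if t in FIXED_TARGETS:
                significant[t] = bool(wald_pvalue(full, t) < alpha)

    conv_ri = conv_none = None
    if need_lrt:
        try:
            ri = fit(
                data,
                ModelStructure(random_intercept=True, random_slope=False),
                n_quadrature=n_quadrature,
                compute_se=False,
            )
        except Exception:
            ri = None
        try:
            plain = fit(
                data,
                ModelStructure(random_intercept=False, random_slope=False),
                n_quadrature=n_quadrature,
                compute_se=False,
            )
        except Exception:
            plain = None
        conv_ri = bool(ri is not None and ri.converged)
        conv_none = bool(plain is not None and plain.converged)
        if "sigma0_sq" in targets and conv_ri and conv_none:
            res = lrt_random_effect(
                data, "intercept_variance", full_fit=ri, reduced_fit=plain
            )
            significant["sigma0_sq"] = bool(res.p_value < alpha)
        if "sigma1_sq" in targets and conv_full and conv_ri:
            # reuse the full (slope) fit; compute_se cost already paid
            res = lrt_random_effect(
                data, "slope_variance", full_fit=full, reduced_fit=ri
            )
            significant["sigma1_sq"] = bool(res.p_value < alpha)

    return ReplicationOutcome(
        significant=significant,
        converged_full=conv_full,
        converged_intercept_only=conv_ri,
        converged_no_random=conv_none,
    )


@dataclass
class PowerResult:
    """Monte-Carlo power for one scenario at one (N1, N2) grid point."""

    scenario_label: str
    n_level1: int
    n_level2: int
    power: dict[str, float]
    mc_se: dict[str, float]
    n_converged: dict[str, int]
    n_replications: int
    alpha: float
    seed: int

    def rows(self) -> list[dict]:
        return [
            {
                "scenario": self.scenario_label,
                "n_level2": self.n_level2,
                "n_level1": self.n_level1,
                "target": t,
                "power": self.power[t],
                "mc_se": self.mc_se[t],
                "n_converged": self.n_converged[t],
                "n_replications": self.n_replications,
                "alpha": self.alpha,
                "seed": self.seed,
            }
            for t in self.power
        ]


def estimate_power(
    scenario: ScenarioSpec,
    n_level1: int,
    n_level2: int,
    n_replications: int,
    *,
    alpha: float = 0.05,
    seed: int = 0,
    targets: tuple[str, ...] = ALL_TARGETS,
    n_quadrature: int = 7,
    stream_key: tuple[int, ...] = (),
) -> PowerResult:
    """Aggregate run_replication over independent substreams.

    Power per target = significant / converged; both counts are retained.
    A target with zero converged replications reports power and SE of NaN
    rather than raising.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    hits = {t: 0 for t in targets}
    used = {t: 0 for t in targets}
    for r in range(int(n_replications)):
        rng = _substream(seed, (*stream_key, r))
        out = run_replication(
            scenario,
            n_level1,
            n_level2,
            rng,
            alpha=alpha,
            targets=targets,
            n_quadrature=n_quadrature,
        )
        for t in targets:
            ind = out.significant[t]
            if ind is not None:
                used[t] += 1
                hits[t] += int(ind)
    power = {
        t: (hits[t] / used[t]) if used[t] > 0 else float("nan") for t in targets
    }
    mc_se = {
        t: mc_standard_error(power[t], used[t]) if used[t] > 0 else float("nan")
        for t in targets
    }
    return PowerResult(
        scenario_label=scenario.label,
        n_level1=int(n_level1),
        n_level2=int(n_level2),
        power=power,
        mc_se=mc_se,
        n_converged=used,
        n_replications=int(n_replications),
        alpha=alpha,
        seed=int(seed),
    )


@dataclass
class PowerTable:
    """Power results over a full N1 x N2 grid for one scenario."""

    results: list[PowerResult]
    scenario_label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([row for r in self.results for row in r.rows()])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dataframe().to_dict(orient="records"), fh, indent=1)

    def lookup(self, n_level1: int, n_level2: int) -> PowerResult:
        for r in self.results:
            if r.n_level1 == n_level1 and r.n_level2 == n_level2:
                return r
        raise KeyError(f"no grid cell (n_level1={n_level1}, n_level2={n_level2})")


#: desk-scale default grids (the full study grid is N1=10..100 by 1)
DEFAULT_N1_GRID = tuple(range(10, 101, 10))
DEFAULT_N2_GRID = (10, 30, 50, 70, 90, 110)


def power_curve(
    scenario: ScenarioSpec,
    n_level1_values=DEFAULT_N1_GRID,
    n_level2_values=DEFAULT_N2_GRID,
    n_replications: int = 1000,
    *,
    alpha: float = 0.05,
    seed: int = 0,
    targets: tuple[str, ...] = ALL_TARGETS,
    n_quadrature: int = 7,
    n_jobs: int = 1,
) -> PowerTable:
    """Evaluate the full Cartesian grid of sample sizes.

    Every (cell, replication) pair has its own substream, so serial and
    parallel execution produce identical tables.
    """
    n1s = [int(v) for v in n_level1_values]
    n2s = [int(v) for v in n_level2_values]
    if not n1s or not n2s:
        raise ValueError("sample-size grids must be nonempty")
    cells = [(i, n1, n2) for i, (n2, n1) in enumerate(
        (n2, n1) for n2 in n2s for n1 in n1s
    )]

    def one(cell):
        i, n1, n2 = cell
        return estimate_power(
            scenario,
            n1,
            n2,
            n_replications,
            alpha=alpha,
            seed=seed,
            targets=targets,
            n_quadrature=n_quadrature,
            stream_key=(i,),
        )

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in cells)
    else:
        results = [one(c) for c in cells]
    return PowerTable(results=list(results), scenario_label=scenario.label)


def plot_power_table(table: PowerTable, path=None, *, reference: float = 0.80):
    """Power-vs-N1 panels facetted by N2, with a horizontal reference line.

    Returns the matplotlib Figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = table.to_dataframe()
    n2s = sorted(df["n_level2"].unique())
    fig, axes = plt.subplots(
        1, len(n2s), figsize=(3.0 * len(n2s), 3.2), sharey=True, squeeze=False
    )
    for ax, n2 in zip(axes[0], n2s):
        sub = df[df["n_level2"] == n2]
        for target, grp in sub.groupby("target"):
            grp = grp.sort_values("n_level1")
            ax.plot(grp["n_level1"], grp["power"], marker="o", ms=3, label=target)
        ax.axhline(reference, color="grey", lw=1, ls="--")
        ax.set_title(f"N2 = {n2}", fontsize=9)
        ax.set_xlabel("N1 (units per cluster)")
        ax.set_ylim(0, 1.02)
    axes[0][0].set_ylabel("power")
    axes[0][-1].legend(fontsize=7)
    fig.suptitle(table.scenario_label, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
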