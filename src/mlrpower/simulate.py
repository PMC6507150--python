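"""Simulation of balanced two-level binary-outcome datasets.

For each cluster j the cluster-level predictor z_j and random effects
(u0j, u1j) are drawn, then each of the n_level1 rows draws its unit-level
predictor x_ij and an outcome y_ij ~ Bernoulli(expit(eta_ij)) with

    eta_ij = (gamma00 + gamma01 z_j + u0j) + (gamma10 + gamma11 z_j + u1j) x_ij.

Everything — predictors included — is redrawn on every call, so repeated
simulation is full generative repetition of the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_core import (
    PredictorSpec,
    ScenarioSpec,
    coefficient_for,
    effect_size_preset,
    interaction_coefficient,
    intercept_variance_from_icc,
)

__all__ = [
    "SimulatedDataset",
    "sample_predictor",
    "simulate_dataset",
    "case_preset",
    "CASE_IDS",
]

CSV_COLUMNS = ("cluster_id", "x", "z", "y")


@dataclass
class SimulatedDataset:
    """One realized balanced two-level dataset in long format.

    Arrays are row-aligned with length n_level1 * n_level2; rows are grouped
    by cluster (cluster 0 first).  ``z`` is replicated to rows and constant
    within each cluster.
    """

    cluster_id: np.ndarray
    x: np.ndarray
    z: np.ndarray
    y: np.ndarray
    n_level1: int
    n_level2: int

    def __post_init__(self) -> None:
        n = self.n_level1 * self.n_level2
        for name in ("cluster_id", "x", "z", "y"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(
                    f"{name} must have shape ({n},) for a balanced "
                    f"{self.n_level2}x{self.n_level1} design, got {arr.shape}"
                )
            setattr(self, name, arr)
        self.cluster_id = self.cluster_id.astype(np.int64)
        self.y = self.y.astype(np.int64)
        counts = np.bincount(self.cluster_id, minlength=self.n_level2)
        if self.cluster_id.min() < 0 or self.cluster_id.max() >= self.n_level2:
            raise ValueError("cluster_id out of range [0, n_level2)")
        if not np.all(counts == self.n_level1):
            raise ValueError("design is unbalanced: unequal rows per cluster")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        # z constant within cluster
        order = np.argsort(self.cluster_id, kind="stable")
        z_sorted = self.z[order].reshape(self.n_level2, self.n_level1)
        if not (z_sorted == z_sorted[:, :1]).all():
            raise ValueError("z must be constant within each cluster")

    @property
    def n_rows(self) -> int:
        return self.n_level1 * self.n_level2

    def cluster_z(self) -> np.ndarray:
        """The cluster-level predictor, one value per cluster."""
        out = np.empty(self.n_level2)
        out[self.cluster_id] = self.z
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster_id": self.cluster_id, "x": self.x, "z": self.z, "y": self.y}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimulatedDataset":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        cluster = frame["cluster_id"].to_numpy()
        n_level2 = int(np.unique(cluster).size)
        n_level1 = len(frame) // n_level2
        return cls(
            cluster_id=cluster,
            x=frame["x"].to_numpy(dtype=float),
            z=frame["z"].to_numpy(dtype=float),
            y=frame["y"].to_numpy(),
            n_level1=n_level1,
            n_level2=n_level2,
        )

    @classmethod
    def from_csv(cls, path) -> "SimulatedDataset":
        return cls.from_frame(pd.read_csv(path))


def sample_predictor(
    spec: PredictorSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n i.i.d. predictor values under ``spec``.

    binary -> Bernoulli(incidence) coded {0,1}; normal -> standard normal;
    chi_square -> chi-square(df), centered/scaled to mean 0 variance 1 only
    if ``spec.standardize`` is set (raw draws are the default).
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.kind == "binary":
        return (rng.random(n) < spec.incidence).astype(float)
    if spec.kind == "normal":
        return rng.standard_normal(n)
    draws = rng.chisquare(spec.df, n)
    if spec.standardize:
        draws = (draws - spec.df) / np.sqrt(2.0 * spec.df)
    return draws


def _exact_split_binary(spec: PredictorSpec, n: int, rng: np.random.Generator):
    """Deterministic count of 1s (round(incidence * n)), randomly placed."""
    ones = int(round(spec.incidence * n))
    values = np.zeros(n)
    values[:ones] = 1.0
    return rng.permutation(values)


def simulate_dataset(
    scenario: ScenarioSpec,
    n_level1: int,
    n_level2: int,
    rng: np.random.Generator,
    *,
    level2_exact_split: bool = False,
) -> SimulatedDataset:
    """Simulate one balanced dataset of n_level2 clusters x n_level1 rows.

    Parameters
    ----------
    level2_exact_split
        For a binary cluster-level predictor, assign exactly
        round(incidence * n_level2) clusters to the 1-group instead of
        i.i.d. Bernoulli draws.  Off by default.
    """
    n_level1 = int(n_level1)
    n_level2 = int(n_level2)
    if n_level1 < 1:
        raise ValueError("n_level1 must be >= 1")
    if n_level2 < 2:
        raise ValueError("n_level2 must be >= 2")

    fixed = scenario.fixed
    cov = scenario.random_cov.matrix()

    if level2_exact_split and scenario.level2_predictor.is_binary:
        z_cluster = _exact_split_binary(scenario.level2_predictor, n_level2, rng)
    else:
        z_cluster = sample_predictor(scenario.level2_predictor, n_level2, rng)

    # (u0, u1) via Cholesky-like factor; eigh fallback covers singular covs
    try:
        chol = np.linalg.cholesky(cov + 1e-14 * np.eye(2))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValueError("random-effects covariance is not PSD") from exc
    u = rng.standard_normal((n_level2, 2)) @ chol.T

    x = sample_predictor(scenario.level1_predictor, n_level1 * n_level2, rng)

    cluster_id = np.repeat(np.arange(n_level2), n_level1)
    b0 = fixed.gamma00 + fixed.gamma01 * z_cluster + u[:, 0]
    b1 = fixed.gamma10 + fixed.gamma11 * z_cluster + u[:, 1]
    eta = b0[cluster_id] + b1[cluster_id] * x
    y = (rng.random(eta.size) < expit(eta)).astype(np.int64)

    return SimulatedDataset(
        cluster_id=cluster_id,
        x=x,
        z=z_cluster[cluster_id],
        y=y,
        n_level1=n_level1,
        n_level2=n_level2,
    )


# -- named study scenarios ---------------------------------------------------

#: incidence of the unbalanced binary predictor and df of the skewed
#: chi-square predictor at each severity level
_SEVERITY = {"moderate": {"incidence": 0.30, "df": 5}, "extreme": {"incidence": 0.10, "df": 1}}

CASE_IDS = (
    "benchmark",
    "case1_unbalancedL2",
    "case1_skewedL1",
    "case2",
    "case3",
    "normalL1_extremeL2",
    "skewedL1_balancedL2",
)


def _scenario(l1: PredictorSpec, l2: PredictorSpec, magnitude: str, label: str) -> ScenarioSpec:
    _, cov = effect_size_preset(magnitude)
    fixed_kwargs = {
        "gamma00": 0.0,
        "gamma10": coefficient_for(l1.kind, magnitude),
        "gamma01": coefficient_for(l2.kind, magnitude),
        "gamma11": interaction_coefficient(magnitude),
    }
    from .model_core import FixedEffects

    return ScenarioSpec(
        fixed=FixedEffects(**fixed_kwargs),
        random_cov=cov,
        level1_predictor=l1,
        level2_predictor=l2,
        label=label,
    )


def case_preset(
    case_id: str, magnitude: str = "medium", severity: str | None = None
) -> ScenarioSpec:
    """Named study scenarios.

    benchmark
        Balanced binary x (50% incidence) + standard-normal z.
    case2
        Unbalanced binary x + skewed chi-square z, at the given severity
        (moderate: 30% incidence / df 5; extreme: 10% incidence / df 1).
    case3
        Skewed chi-square x + unbalanced binary z at the given severity.
    case1_unbalancedL2 / normalL1_extremeL2
        Standard-normal x + extremely unbalanced binary z (10% incidence).
    case1_skewedL1 / skewedL1_balancedL2
        Extremely skewed chi-square x (df 1) + balanced binary z (50%).
    """
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case_id {case_id!r}; expected one of {CASE_IDS}")
    if case_id in ("case2", "case3"):
        if severity not in _SEVERITY:
            raise ValueError(
                f"{case_id} requires severity 'moderate' or 'extreme', got {severity!r}"
            )
        sev = _SEVERITY[severity]

    if case_id == "benchmark":
        l1 = PredictorSpec("binary", incidence=0.5)
        l2 = PredictorSpec("normal")
        label = f"benchmark ({magnitude})"
    elif case_id == "case2":
        l1 = PredictorSpec("binary", incidence=sev["incidence"])
        l2 = PredictorSpec("chi_square", df=sev["df"])
        label = f"case2 {severity} ({magnitude})"
    elif case_id == "case3":
        l1 = PredictorSpec("chi_square", df=sev["df"])
        l2 = PredictorSpec("binary", incidence=sev["incidence"])
        label = f"case3 {severity} ({magnitude})"
    elif case_id in ("case1_unbalancedL2", "normalL1_extremeL2"):
        l1 = PredictorSpec("normal")
        l2 = PredictorSpec("binary", incidence=0.10)
        label = f"normal L1 + extreme-unbalanced L2 ({magnitude})"
    else:  # case1_skewedL1 / skewedL1_balancedL2
        l1 = PredictorSpec("chi_square", df=1)
        l2 = PredictorSpec("binary", incidence=0.5)
        label = f"extreme-skewed L1 + balanced L2 ({magnitude})"
    return _scenario(l1, l2, magnitude, label)
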