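"""Model parameters, effect-size presets and latent-scale ICC arithmetic.

The statistical model is a two-level logistic regression for a binary
outcome :math:`y_{ij}` of unit *i* in cluster *j*:

.. math::

    \\mathrm{logit}(\\pi_{ij}) = \\beta_{0j} + \\beta_{1j} x_{ij},
    \\qquad
    \\beta_{0j} = \\gamma_{00} + \\gamma_{01} z_j + u_{0j},
    \\qquad
    \\beta_{1j} = \\gamma_{10} + \\gamma_{11} z_j + u_{1j},

with a cluster-level predictor :math:`z_j`, a unit-level predictor
:math:`x_{ij}`, and bivariate-normal random effects
:math:`(u_{0j}, u_{1j}) \\sim N(0, \\Sigma_u)`.  The coefficient
:math:`\\gamma_{11}` is the cross-level interaction.

On the latent logistic scale the unit-level residual variance is the
variance of a standard logistic variate, :math:`\\pi^2/3`, so the
intraclass correlation induced by a random-intercept variance
:math:`\\sigma_0^2` is :math:`\\sigma_0^2 / (\\sigma_0^2 + \\pi^2/3)`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "LOGISTIC_RESIDUAL_VARIANCE",
    "FixedEffects",
    "RandomEffectsCov",
    "PredictorSpec",
    "ScenarioSpec",
    "icc_from_intercept_variance",
    "intercept_variance_from_icc",
    "effect_size_preset",
    "chi_square_skewness",
]

#: Variance of a standard logistic distribution: the unit-level residual
#: variance on the latent scale, used everywhere the ICC is computed.
LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3

# Effect-size conventions: binary predictors carry the standardized-mean-
# difference sized coefficient, continuous predictors the correlational one.
_BINARY_COEF = {"medium": 0.5, "large": 0.8}
_CONTINUOUS_COEF = {"medium": 0.3, "large": 0.5}
_INTERACTION_COEF = {"medium": 0.3, "large": 0.5}
_ICC = {"medium": 0.3, "large": 0.5}
_SLOPE_VAR = {"medium": 0.3, "large": 0.5}


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be a finite real number, got {value!r}")
    return value


@dataclass(frozen=True)
class FixedEffects:
    """Fixed-effect coefficients on the log-odds scale.

    Attributes
    ----------
    gamma00 : intercept
    gamma10 : coefficient of the unit-level (Level-1) predictor x
    gamma01 : coefficient of the cluster-level (Level-2) predictor z
    gamma11 : cross-level interaction coefficient (z * x)
    """

    gamma00: float = 0.0
    gamma10: float = 0.0
    gamma01: float = 0.0
    gamma11: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma00", "gamma10", "gamma01", "gamma11"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    def as_dict(self) -> dict[str, float]:
        return {
            "gamma00": self.gamma00,
            "gamma10": self.gamma10,
            "gamma01": self.gamma01,
            "gamma11": self.gamma11,
        }


@dataclass(frozen=True)
class RandomEffectsCov:
    """Covariance of the cluster random effects (u0, u1) on the logit scale.

    The 2x2 matrix [[sigma0_sq, sigma01], [sigma01, sigma1_sq]] must be
    positive semidefinite; zero variances are allowed (degenerate effects).
    """

    sigma0_sq: float
    sigma1_sq: float = 0.0
    sigma01: float = 0.0

    def __post_init__(self) -> None:
        s0 = _require_finite("sigma0_sq", self.sigma0_sq)
        s1 = _require_finite("sigma1_sq", self.sigma1_sq)
        s01 = _require_finite("sigma01", self.sigma01)
        if s0 < 0 or s1 < 0:
            raise ValueError("random-effect variances must be nonnegative")
        # PSD for a symmetric 2x2 with nonnegative diagonal <=> det >= 0
        if s0 * s1 - s01 * s01 < -1e-12:
            raise ValueError(
                "random-effects covariance matrix is not positive semidefinite: "
                f"sigma01={s01} with variances ({s0}, {s1})"
            )
        object.__setattr__(self, "sigma0_sq", s0)
        object.__setattr__(self, "sigma1_sq", s1)
        object.__setattr__(self, "sigma01", s01)

    def matrix(self):
        import numpy as np

        return np.array(
            [[self.sigma0_sq, self.sigma01], [self.sigma01, self.sigma1_sq]]
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma0_sq": self.sigma0_sq,
            "sigma1_sq": self.sigma1_sq,
            "sigma01": self.sigma01,
        }


_PREDICTOR_KINDS = ("binary", "normal", "chi_square")


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal distribution of one predictor.

    kind
        ``binary`` (Bernoulli coded 0/1), ``normal`` (standard normal) or
        ``chi_square`` (chi-square with ``df`` degrees of freedom).
    incidence
        Proportion coded 1; required for, and only valid with, ``binary``.
    df
        Degrees of freedom; required for, and only valid with, ``chi_square``.
    standardize
        Center and scale continuous draws to mean 0, variance 1.  Off by
        default: raw chi-square draws keep their natural variance (2*df),
        mirroring designs that do not control predictor variance.
    """

    kind: str
    incidence: float | None = None
    df: int | None = None
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _PREDICTOR_KINDS:
            raise ValueError(
                f"kind must be one of {_PREDICTOR_KINDS}, got {self.kind!r}"
            )
        if self.kind == "binary":
            if self.incidence is None:
                raise ValueError("binary predictor requires 'incidence'")
            if self.df is not None:
                raise ValueError("binary predictor forbids 'df'")
            inc = float(self.incidence)
            if not 0.0 < inc < 1.0:
                raise ValueError(f"incidence must lie strictly in (0, 1), got {inc}")
            object.__setattr__(self, "incidence", inc)
        elif self.kind == "chi_square":
            if self.df is None:
                raise ValueError("chi_square predictor requires 'df'")
            if self.incidence is not None:
                raise ValueError("chi_square predictor forbids 'incidence'")
            df = int(self.df)
            if df < 1:
                raise ValueError(f"df must be a positive integer, got {self.df}")
            object.__setattr__(self, "df", df)
        else:  # normal
            if self.incidence is not None or self.df is not None:
                raise ValueError("normal predictor takes neither 'incidence' nor 'df'")

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"


@dataclass(frozen=True)
class ScenarioSpec:
    """One fully specified simulation condition.

    Exactly one predictor lives at each level: ``level1_predictor`` is the
    unit-level x, ``level2_predictor`` the cluster-level z.
    """

    fixed: FixedEffects
    random_cov: RandomEffectsCov
    level1_predictor: PredictorSpec
    level2_predictor: PredictorSpec
    label: str = ""

    def with_fixed(self, **changes: float) -> "ScenarioSpec":
        """Return a copy with some fixed-effect coefficients replaced."""
        return replace(self, fixed=replace(self.fixed, **changes))

    # -- flat config mapping ------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"label": self.label}
        d.update(self.fixed.as_dict())
        d.update(self.random_cov.as_dict())
        for prefix, spec in (
            ("level1", self.level1_predictor),
            ("level2", self.level2_predictor),
        ):
            d[f"{prefix}_kind"] = spec.kind
            if spec.incidence is not None:
                d[f"{prefix}_incidence"] = spec.incidence
            if spec.df is not None:
                d[f"{prefix}_df"] = spec.df
            if spec.standardize:
                d[f"{prefix}_standardize"] = True
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "ScenarioSpec":
        m = dict(mapping)
        fixed = FixedEffects(
            gamma00=m.pop("gamma00", 0.0),
            gamma10=m.pop("gamma10", 0.0),
            gamma01=m.pop("gamma01", 0.0),
            gamma11=m.pop("gamma11", 0.0),
        )
        cov = RandomEffectsCov(
            sigma0_sq=m.pop("sigma0_sq", 0.0),
            sigma1_sq=m.pop("sigma1_sq", 0.0),
            sigma01=m.pop("sigma01", 0.0),
        )
        preds = {}
        for prefix in ("level1", "level2"):
            preds[prefix] = PredictorSpec(
                kind=m.pop(f"{prefix}_kind"),
                incidence=m.pop(f"{prefix}_incidence", None),
                df=m.pop(f"{prefix}_df", None),
                standardize=bool(m.pop(f"{prefix}_standardize", False)),
            )
        label = m.pop("label", "")
        if m:
            raise ValueError(f"unrecognized scenario keys: {sorted(m)}")
        return cls(
            fixed=fixed,
            random_cov=cov,
            level1_predictor=preds["level1"],
            level2_predictor=preds["level2"],
            label=label,
        )


def icc_from_intercept_variance(sigma0_sq: float) -> float:
    """Latent-scale intraclass correlation of a random-intercept logistic model.

    ICC = sigma0_sq / (sigma0_sq + pi^2/3), with pi^2/3 the variance of the
    standard logistic distribution playing the role of the unit-level
    residual variance.
    """
    sigma0_sq = float(sigma0_sq)
    if not math.isfinite(sigma0_sq) or sigma0_sq < 0:
        raise ValueError(f"sigma0_sq must be nonnegative, got {sigma0_sq}")
    return sigma0_sq / (sigma0_sq + LOGISTIC_RESIDUAL_VARIANCE)


def intercept_variance_from_icc(icc: float) -> float:
    """Inverse of :func:`icc_from_intercept_variance`.

    Returns the random-intercept variance producing the given latent-scale
    ICC: icc * (pi^2/3) / (1 - icc).
    """
    icc = float(icc)
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    return icc * LOGISTIC_RESIDUAL_VARIANCE / (1.0 - icc)


def effect_size_preset(magnitude: str) -> tuple[FixedEffects, RandomEffectsCov]:
    """Conventional medium/large effect-size parameter sets.

    Assumes the default predictor placement — binary x at Level 1,
    continuous z at Level 2 — so the binary-sized coefficient (0.5 / 0.8)
    goes to gamma10 and the continuous-sized one (0.3 / 0.5) to gamma01.
    ``medium`` sets sigma0_sq = pi^2/7 (ICC 0.3) and sigma1_sq = 0.3;
    ``large`` sets sigma0_sq = pi^2/3 (ICC 0.5) and sigma1_sq = 0.5.
    gamma00 = 0 (baseline prevalence 50%) and sigma01 = 0 in both.
    """
    if magnitude not in _BINARY_COEF:
        raise ValueError(
            f"magnitude must be 'medium' or 'large', got {magnitude!r}"
        )
    fixed = FixedEffects(
        gamma00=0.0,
        gamma10=_BINARY_COEF[magnitude],
        gamma01=_CONTINUOUS_COEF[magnitude],
        gamma11=_INTERACTION_COEF[magnitude],
    )
    cov = RandomEffectsCov(
        sigma0_sq=intercept_variance_from_icc(_ICC[magnitude]),
        sigma1_sq=_SLOPE_VAR[magnitude],
        sigma01=0.0,
    )
    return fixed, cov


def coefficient_for(kind: str, magnitude: str) -> float:
    """Effect-size coefficient keyed to predictor type.

    Binary predictors carry the standardized-mean-difference-sized value
    (0.5 medium, 0.8 large); continuous ones the correlational value
    (0.3 medium, 0.5 large), regardless of the level they occupy.
    """
    table = _BINARY_COEF if kind == "binary" else _CONTINUOUS_COEF
    if magnitude not in table:
        raise ValueError(f"magnitude must be 'medium' or 'large', got {magnitude!r}")
    return table[magnitude]


def interaction_coefficient(magnitude: str) -> float:
    """Cross-level interaction coefficient: 0.3 medium, 0.5 large."""
    if magnitude not in _INTERACTION_COEF:
        raise ValueError(f"magnitude must be 'medium' or 'large', got {magnitude!r}")
    return _INTERACTION_COEF[magnitude]


def chi_square_skewness(df: int) -> float:
    """Population skewness of a chi-square(df) variable: sqrt(8/df)."""
    df = int(df)
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    return math.sqrt(8.0 / df)
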