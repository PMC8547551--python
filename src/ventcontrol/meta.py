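"""Ratio-of-means meta-analysis with heterogeneity diagnostics.

Effect measure: the natural-log ratio of means (log-ROM),
``ln(mean_t / mean_c)``, with the delta-method variance
``sd_t^2/(n_t mean_t^2) + sd_c^2/(n_c mean_c^2)``.  Pooling uses
inverse-variance weighting; between-study variance tau^2 is estimated by
DerSimonian-Laird (truncated at zero) and heterogeneity summarised by
Cochran's Q and I^2.  By default the model is chosen automatically:
random effects when I^2 > 30%, fixed effect otherwise.  Inference is
two-sided normal-theory throughout.

A Hedges-corrected standardised-mean-difference effect is available as a
cross-check on the same pooling machinery, and helpers compute weighted
control-arm statistics, implied absolute differences on the control scale,
weighted-least-squares meta-regression on a study-level moderator, and
leave-one-out sensitivity tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StudySummary",
    "StudyEffect",
    "PooledResult",
    "MetaRegressionResult",
    "rom_effect",
    "smd_effect",
    "pool",
    "weighted_control_stats",
    "absolute_difference",
    "meta_regress",
    "leave_one_out",
]


@dataclass(frozen=True)
class StudySummary:
    """Two-arm summary statistics of one study (treated vs. control)."""

    study_id: str
    mean_t: float
    sd_t: float
    n_t: int
    mean_c: float
    sd_c: float
    n_c: int
    moderators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.sd_t > 0 and self.sd_c > 0):
            raise ValueError(f"study {self.study_id!r}: SDs must be positive")
        if self.n_t < 2 or self.n_c < 2:
            raise ValueError(f"study {self.study_id!r}: need n >= 2 per arm")


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect on a log (or SMD) scale with its sampling variance."""

    effect: float
    variance: float
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"effect variance must be positive, got {self.variance!r}")


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect with heterogeneity diagnostics.

    ``effect``/``se``/``ci_low``/``ci_high``/``p_value`` are on the pooling
    scale (log-ROM or SMD).  For log-ratio effects, :attr:`rom` and
    :attr:`rom_ci` back-transform with ``exp``.  ``weights`` are the
    normalised study weights of the model actually used.
    """

    effect: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    q: float
    df: int
    i2: float
    tau2: float
    method: str
    k: int
    weights: np.ndarray

    @property
    def rom(self) -> float:
        return math.exp(self.effect)

    @property
    def rom_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def as_record(self) -> dict[str, float]:
        lo, hi = self.rom_ci
        return {
            "k": self.k,
            "effect": self.effect,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "rom": self.rom,
            "rom_ci_low": lo,
            "rom_ci_high": hi,
            "p_value": self.p_value,
            "q": self.q,
            "df": self.df,
            "i2": self.i2,
            "tau2": self.tau2,
            "method": self.method,
        }


def rom_effect(s: StudySummary) -> StudyEffect:
    """Log ratio-of-means effect with delta-method variance."""
    if not (s.mean_t > 0 and s.mean_c > 0):
        raise ValueError(
            f"study {s.study_id!r}: ratio of means requires positive arm means"
        )
    log_rom = math.log(s.mean_t / s.mean_c)
    var = s.sd_t**2 / (s.n_t * s.mean_t**2) + s.sd_c**2 / (s.n_c * s.mean_c**2)
    return StudyEffect(effect=log_rom, variance=var, study_id=s.study_id)


def smd_effect(s: StudySummary) -> StudyEffect:
    """Hedges-corrected standardised mean difference, poolable by :func:`pool`."""
    df = s.n_t + s.n_c - 2
    sp2 = ((s.n_t - 1) * s.sd_t**2 + (s.n_c - 1) * s.sd_c**2) / df
    if sp2 <= 0:
        raise ValueError(f"study {s.study_id!r}: zero pooled SD")
    d = (s.mean_t - s.mean_c) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)  # small-sample bias correction
    g = j * d
    n_total = s.n_t + s.n_c
    var = n_total / (s.n_t * s.n_c) + g**2 / (2.0 * n_total)
    return StudyEffect(effect=g, variance=var, study_id=s.study_id)


I2_RANDOM_THRESHOLD = 30.0  # percent; above this, auto mode pools with random effects


def pool(
    effects: list[StudyEffect],
    method: str = "auto",
    alpha: float = 0.05,
) -> PooledResult:
    """Inverse-variance pooling with DerSimonian-Laird random effects.

    ``method``: ``"fixed"``, ``"random"``, or ``"auto"`` (random effects
    if and only if I^2 > 30%).  Heterogeneity statistics are always computed
    from the fixed-effect fit: ``Q = sum w (y - yhat)^2`` with ``w = 1/v``,
    ``I^2 = max(0, (Q - df)/Q) * 100`` and
    ``tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))``.
    """
    if method not in ("auto", "fixed", "random"):
        raise ValueError(f"method must be auto|fixed|random, got {method!r}")
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    y = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    k = len(effects)
    w = 1.0 / v
    est_fe = float(np.sum(w * y) / np.sum(w))
    df = k - 1
    q = float(np.sum(w * (y - est_fe) ** 2))
    if k < 2 or q <= 0:
        i2, tau2 = 0.0, 0.0
    else:
        i2 = max(0.0, (q - df) / q * 100.0)
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c)

    use_random = method == "random" or (method == "auto" and i2 > I2_RANDOM_THRESHOLD)
    if use_random:
        w_used = 1.0 / (v + tau2)
        est = float(np.sum(w_used * y) / np.sum(w_used))
    else:
        w_used, est = w, est_fe
    se = float(math.sqrt(1.0 / np.sum(w_used)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * stats.norm.sf(abs(est / se))
    return PooledResult(
        effect=est,
        se=se,
        ci_low=est - z * se,
        ci_high=est + z * se,
        p_value=float(p),
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        method="random" if use_random else "fixed",
        k=k,
        weights=w_used / np.sum(w_used),
    )


def weighted_control_stats(
    studies: list[StudySummary],
    weights: np.ndarray | list[float],
    sd_mode: str = "weighted_mean",
) -> tuple[float, float]:
    """Weight-averaged control-arm mean and SD using meta-analysis weights.

    ``sd_mode="weighted_mean"`` averages the study SDs directly;
    ``"pooled"`` averages the variances and takes the square root.
    """
    weights = np.asarray(weights, float)
    if len(studies) != weights.size:
        raise ValueError(
            f"{len(studies)} studies but {weights.size} weights"
        )
    wn = weights / weights.sum()
    means = np.array([s.mean_c for s in studies])
    sds = np.array([s.sd_c for s in studies])
    mean_wt = float(np.sum(wn * means))
    if sd_mode == "weighted_mean":
        sd_wt = float(np.sum(wn * sds))
    elif sd_mode == "pooled":
        sd_wt = float(math.sqrt(np.sum(wn * sds**2)))
    else:
        raise ValueError(f"sd_mode must be weighted_mean|pooled, got {sd_mode!r}")
    return mean_wt, sd_wt


def absolute_difference(
    rom: float | tuple[float, float, float] | PooledResult,
    mean_wt: float,
) -> tuple[float, float, float] | float:
    """Implied absolute difference on the control scale: ``ROM * mean - mean``.

    Accepts a scalar ROM (returns a scalar), a ``(point, low, high)`` triple,
    or a :class:`PooledResult` on the log-ROM scale (returns a triple).
    """
    if not mean_wt > 0:
        raise ValueError(f"mean_wt must be positive, got {mean_wt!r}")
    if isinstance(rom, PooledResult):
        lo, hi = rom.rom_ci
        rom = (rom.rom, lo, hi)
    if isinstance(rom, tuple):
        point, lo, hi = rom
        return (point * mean_wt - mean_wt, lo * mean_wt - mean_wt, hi * mean_wt - mean_wt)
    return rom * mean_wt - mean_wt


@dataclass(frozen=True)
class MetaRegressionResult:
    """WLS slope of effect size on a moderator, with normal-theory inference."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    intercept: float
    tau2: float


def meta_regress(
    effects: list[StudyEffect],
    moderator: np.ndarray | list[float],
    tau2: float | None = None,
    alpha: float = 0.05,
) -> MetaRegressionResult:
    """Weighted least squares of effects on one moderator.

    Weights are ``1/(variance + tau^2)`` with tau^2 from the intercept-only
    DerSimonian-Laird fit unless given.  The coefficient covariance is the
    standard fixed-scale meta-regression form ``(X' W X)^{-1}`` (no residual
    rescaling), matching normal-theory meta-regression.
    """
    x = np.asarray(moderator, float)
    if len(effects) != x.size:
        raise ValueError(f"{len(effects)} effects but {x.size} moderator values")
    if len(effects) < 3:
        raise ValueError("meta-regression requires at least 3 studies")
    if np.ptp(x) == 0:
        raise ValueError("moderator is constant: design matrix is rank-deficient")
    y = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    if tau2 is None:
        tau2 = pool(effects, method="random").tau2
    w = 1.0 / (v + tau2)
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    slope, se = float(beta[1]), float(math.sqrt(cov[1, 1]))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return MetaRegressionResult(
        slope=slope,
        se=se,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        p_value=float(2.0 * stats.norm.sf(abs(slope / se))),
        intercept=float(beta[0]),
        tau2=float(tau2),
    )


def leave_one_out(
    studies: list[StudySummary],
    effect_fn=rom_effect,
    method: str = "auto",
) -> dict[str, PooledResult]:
    """Re-pool with each study omitted in turn, keyed by the omitted id."""
    if len(studies) < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    out: dict[str, PooledResult] = {}
    for omit in studies:
        rest = [effect_fn(s) for s in studies if s is not omit]
        out[omit.study_id] = pool(rest, method=method)
    return out
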