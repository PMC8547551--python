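"""Synthetic two-arm study generator for exercising the meta-analysis engine.

No per-study summary data are published for the pooled control-of-breathing
outcomes, so the engine is validated on simulated study sets with a known
true ratio of means and between-study variance.  Defaults emulate a pooled
eupneic-paCO2-like outcome: control means around 38.2 mmHg (between-study SD
3.7 mmHg), a true ROM of 0.85 (a 15% reduction, the pooled apnea-threshold
effect), homogeneous studies (tau^2 = 0), 20 studies of 50 subjects per arm.

Each study draws a true log-ROM from ``Normal(ln ROM, tau^2)``, a control
mean from the configured between-study distribution, and a within-arm
coefficient of variation; the *observed* arm means and SDs are sample
statistics of actual per-subject draws, so the small-sample noise that the
delta-method variance formula must absorb is genuinely present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .meta import StudySummary, pool, rom_effect

__all__ = ["SimConfig", "RecoverySummary", "generate_studies", "recovery_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study set.

    true_rom : true ratio of means (treated/control), > 0.
    tau2 : between-study variance of the log-ROM, >= 0.
    n_studies : number of studies per set.
    n_range : inclusive (low, high) per-arm sample-size range.
    control_mean / control_sd : between-study location and spread of the
        control-arm mean (units of the outcome, e.g. mmHg).
    cv_range : within-arm coefficient-of-variation range, drawn per study.
    distribution : "normal" or "lognormal" per-subject outcomes.
    seed : mandatory integer seed; generation is deterministic given it.
    """

    true_rom: float = 0.85
    tau2: float = 0.0
    n_studies: int = 20
    n_range: tuple[int, int] = (50, 50)
    control_mean: float = 38.2
    control_sd: float = 3.7
    cv_range: tuple[float, float] = (0.08, 0.15)
    distribution: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_rom > 0:
            raise ValueError("true_rom must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError("n_range must be (low, high) with low >= 2")
        if not self.control_mean > 0 or self.control_sd < 0:
            raise ValueError("control mean must be positive, its SD non-negative")
        if not (0 < self.cv_range[0] <= self.cv_range[1]):
            raise ValueError("cv_range must be positive and ordered")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def _draw_arm(
    rng: np.random.Generator, mu: float, sigma: float, n: int, distribution: str
) -> np.ndarray:
    if distribution == "normal":
        return rng.normal(mu, sigma, size=n)
    # lognormal parameterised to match the target mean and SD exactly
    s2 = math.log(1.0 + (sigma / mu) ** 2)
    return rng.lognormal(math.log(mu) - s2 / 2.0, math.sqrt(s2), size=n)


def generate_studies(cfg: SimConfig) -> list[StudySummary]:
    """One synthetic study set; byte-identical across calls with the same config."""
    rng = np.random.default_rng(cfg.seed)
    studies: list[StudySummary] = []
    for i in range(cfg.n_studies):
        theta = rng.normal(math.log(cfg.true_rom), math.sqrt(cfg.tau2))
        mu_c = rng.normal(cfg.control_mean, cfg.control_sd)
        if mu_c <= 0:
            raise ValueError(
                "configuration implies a non-positive control mean; "
                "shrink control_sd or raise control_mean"
            )
        mu_t = mu_c * math.exp(theta)
        cv = rng.uniform(*cfg.cv_range)
        n_t = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        n_c = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        xt = _draw_arm(rng, mu_t, cv * mu_t, n_t, cfg.distribution)
        xc = _draw_arm(rng, mu_c, cv * mu_c, n_c, cfg.distribution)
        if xt.mean() <= 0 or xc.mean() <= 0:
            raise ValueError(
                "simulated arm produced a non-positive observed mean; "
                "use a smaller cv_range or the lognormal distribution"
            )
        studies.append(
            StudySummary(
                study_id=f"study_{i + 1:03d}",
                mean_t=float(xt.mean()),
                sd_t=float(xt.std(ddof=1)),
                n_t=n_t,
                mean_c=float(xc.mean()),
                sd_c=float(xc.std(ddof=1)),
                n_c=n_c,
            )
        )
    return studies


@dataclass(frozen=True)
class RecoverySummary:
    """Calibration metrics aggregated over repeated generate-and-pool runs."""

    reps: int
    bias: float  # mean pooled log-ROM minus true log-ROM
    rmse: float  # of the pooled log-ROM
    coverage: float  # fraction of reps whose 95% CI covers the true ROM
    mean_i2: float
    median_tau2: float


def recovery_experiment(
    cfg: SimConfig, reps: int, method: str = "auto"
) -> RecoverySummary:
    """Repeat generate -> pool ``reps`` times and aggregate calibration metrics.

    Per-rep seeds are derived deterministically from ``cfg.seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rep_seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=reps)
    true_log = math.log(cfg.true_rom)
    est = np.empty(reps)
    covered = np.empty(reps, dtype=bool)
    i2 = np.empty(reps)
    tau2 = np.empty(reps)
    for r in range(reps):
        studies = generate_studies(replace(cfg, seed=int(rep_seeds[r])))
        res = pool([rom_effect(s) for s in studies], method=method)
        est[r] = res.effect
        covered[r] = res.ci_low <= true_log <= res.ci_high
        i2[r] = res.i2
        tau2[r] = res.tau2
    return RecoverySummary(
        reps=reps,
        bias=float(est.mean() - true_log),
        rmse=float(np.sqrt(np.mean((est - true_log) ** 2))),
        coverage=float(covered.mean()),
        mean_i2=float(i2.mean()),
        median_tau2=float(np.median(tau2)),
    )
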