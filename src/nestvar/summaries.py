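"""Posterior summaries: modes, credible intervals, support categories,
year-specific effects, back-transformed effect sizes, correlations among
random effects and variance partitions.

Effects are summarized by the posterior mode (Gaussian-kernel density,
Silverman bandwidth, argmax on a 512-point grid) with equal-tailed 95%
credible intervals, and classified as *strong* (CI excludes zero),
*moderate* (at most 15% of the posterior mass on the minority side of zero
— i.e. over five-fold support for the estimated direction) or *none*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .dhglm import PosteriorResult

__all__ = [
    "EffectSummary",
    "posterior_mode",
    "support_category",
    "back_transform",
    "year_effects",
    "random_effect_correlations",
    "variance_partition",
]

MIN_DRAWS = 400


def posterior_mode(draws: np.ndarray) -> float:
    """KDE argmax over the draw range (deterministic given the draws)."""
    draws = np.asarray(draws, float).ravel()
    if len(draws) < MIN_DRAWS:
        raise ValueError(f"posterior_mode needs >= {MIN_DRAWS} draws, got {len(draws)}")
    if np.ptp(draws) == 0.0:
        return float(draws[0])
    kde = gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def support_category(draws: np.ndarray) -> str:
    """strong / moderate / none by CI exclusion and posterior mass near zero.

    strong: the equal-tailed 95% CI excludes zero; moderate: the minority
    side of zero holds at most 15% of the mass (>= five-fold directional
    support); none: anything weaker.
    """
    draws = np.asarray(draws, float).ravel()
    lo, hi = np.quantile(draws, [0.025, 0.975])
    if lo > 0 or hi < 0:
        return "strong"
    p_minor = min(float(np.mean(draws > 0)), float(np.mean(draws < 0)))
    return "moderate" if p_minor <= 0.15 else "none"


def back_transform(log_value: float, unit: str = "minutes") -> float:
    """exp(log-minutes) -> minutes or hours (rounding is presentation-only)."""
    minutes = float(np.exp(log_value))
    if unit == "minutes":
        return minutes
    if unit == "hours":
        return minutes / 60.0
    raise ValueError(f"unknown unit {unit!r}")


@dataclass
class EffectSummary:
    """Mode, 95% CI and support category for one reported quantity.

    A KDE mode can fall outside an equal-tailed CI for skewed posteriors;
    that is flagged (``mode_outside_ci``), not fatal.
    """

    name: str
    mode: float
    ci_low: float
    ci_high: float
    support: str
    scale: str

    @property
    def mode_outside_ci(self) -> bool:
        return not (self.ci_low <= self.mode <= self.ci_high)

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray, scale: str) -> "EffectSummary":
        draws = np.asarray(draws, float).ravel()
        lo, hi = np.quantile(draws, [0.025, 0.975])
        return cls(
            name=name,
            mode=posterior_mode(draws),
            ci_low=float(lo),
            ci_high=float(hi),
            support=support_category(draws),
            scale=scale,
        )


def _year_index(result: PosteriorResult, year) -> int:
    labels = list(result.meta["year_labels"])
    if year not in labels:
        raise KeyError(f"year {year!r} not among fitted years {labels}")
    return labels.index(year)


def year_effects(result: PosteriorResult, year) -> dict[str, EffectSummary]:
    """Year-specific intercept (log-minutes), age slope and sigma_exp.

    sigma_exp is the year's residual SD of log IVI at baseline covariates,
    reported on the exponentiated scale: exp(g0 + v_year).
    """
    i = _year_index(result, year)
    if "effects[year:mu_intercept]" not in result.draws:
        raise KeyError(f"spec {result.spec.name!r} has no year-level mean intercept")
    beta_mu = result.stacked("beta_mu")
    beta_sigma = result.stacked("beta_sigma")
    intercept = beta_mu[:, 0] + result.stacked("effects[year:mu_intercept]")[:, i]
    out = {
        "intercept": EffectSummary.from_draws(f"intercept[{year}]", intercept, "log_minutes")
    }
    slope = beta_mu[:, 1]
    if "effects[year:mu_age]" in result.draws:
        slope = slope + result.stacked("effects[year:mu_age]")[:, i]
    out["age_slope"] = EffectSummary.from_draws(f"age_slope[{year}]", slope, "log_minutes")
    sig = beta_sigma[:, 0]
    if "effects[year:sigma_intercept]" in result.draws:
        sig = sig + result.stacked("effects[year:sigma_intercept]")[:, i]
    out["sigma_exp"] = EffectSummary.from_draws(f"sigma_exp[{year}]", np.exp(sig), "sd_log_ivi")
    return out


_CORR_LABELS = {
    ("mu_intercept", "mu_age"): "rho(intercept,slope)",
    ("mu_intercept", "sigma_intercept"): "rho(intercept,log_sigma)",
    ("mu_age", "sigma_intercept"): "rho(slope,log_sigma)",
    ("mu_intercept", "mu_brood"): "rho(intercept,brood_slope)",
    ("mu_age", "mu_brood"): "rho(slope,brood_slope)",
    ("mu_brood", "sigma_intercept"): "rho(brood_slope,log_sigma)",
}


def random_effect_correlations(result: PosteriorResult) -> dict[str, EffectSummary]:
    """Summaries of the estimated random-effect correlation entries.

    Sign convention: a negative rho(intercept, log_sigma) means groups that
    work harder (lower intercept, shorter IVIs) are *more* variable.
    """
    if not result.spec.correlated:
        raise ValueError(f"spec {result.spec.name!r} does not estimate covariances")
    out = {}
    for name in result.draws:
        if not name.startswith("corr["):
            continue
        inner = name[len("corr[") : -1]
        _, terms = inner.split(":")
        t1, t2 = terms.split(",")
        label = _CORR_LABELS.get((t1, t2), name)
        out[label] = EffectSummary.from_draws(label, result.stacked(name), "correlation")
    return out


def variance_partition(result: PosteriorResult) -> dict[str, np.ndarray]:
    """Per-draw share of total log-IVI variance for each random term.

    Intercept terms contribute sd^2; slope terms sd^2 * mean(x^2) over the
    observed standardized covariate; the residual is E[sigma_i^2] averaged
    over the observed covariate distribution (so sigma-part effects are
    inside the residual share).  Shares sum to one for every draw.
    """
    resid = np.asarray(result.meta["resid_var"], float)
    comps: dict[str, np.ndarray] = {}
    for name in result.draws:
        if not name.startswith("sd["):
            continue
        inner = name[len("sd[") : -1]
        group, term = inner.split(":")
        if term == "sigma_intercept":
            continue  # folded into the residual via E[sigma^2]
        sd = result.stacked(name)
        var = sd**2
        if term == "mu_age":
            var = var * result.meta["mean_age_s_sq"]
        elif term == "mu_brood":
            var = var * result.meta["mean_brood_s_sq"]
        comps[f"{group}:{term}"] = var
    total = resid + sum(comps.values())
    shares = {k: v / total for k, v in comps.items()}
    shares["residual"] = resid / total
    return shares
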