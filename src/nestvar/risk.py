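"""Variance-sensitive foraging: shortfall probabilities and patch preference.

Two reward options with equal means but different variances are not
equivalent to a forager that must clear an energetic requirement: when the
requirement exceeds the mean, the more variable option gives the higher
probability of meeting it (variance-prone); when the requirement is below
the mean, the less variable option is safer (variance-averse).  Rewards are
modeled as Normal(mean, sd).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["RewardOption", "shortfall_probability", "preferred_option"]


@dataclass(frozen=True)
class RewardOption:
    label: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def shortfall_probability(option: RewardOption, requirement: float) -> float:
    """P(reward < requirement) under Normal(mean, sd); degenerate at sd=0."""
    if option.sd == 0:
        return float(option.mean < requirement)
    return float(norm.cdf(requirement, loc=option.mean, scale=option.sd))


def preferred_option(options: tuple[RewardOption, RewardOption], requirement: float) -> str:
    """Label of the option minimizing shortfall probability; ties -> 'indifferent'."""
    a, b = options
    pa = shortfall_probability(a, requirement)
    pb = shortfall_probability(b, requirement)
    if pa == pb:
        return "indifferent"
    return a.label if pa < pb else b.label
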