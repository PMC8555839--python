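"""Closed-form crosswise-model (CWM) and direct-question (DQ) estimators,
and the Bayes conditional-probability privacy analysis.

The crosswise design pairs the sensitive statement with an innocuous
statement of known prevalence ``p`` (here: being born in November or
December, p = .158 from official birth statistics).  Respondents only report
whether *both or neither* statement is true, or *exactly one* is.  With
``lambda`` the observed proportion choosing "both/none", the prevalence of
the sensitive attribute is estimated by

    pi_hat = (lambda + p - 1) / (2p - 1),        p != 1/2

with delta-method standard error sqrt(lambda(1-lambda)/n) / |2p - 1|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CwmDesign",
    "PrevalenceEstimate",
    "PrivacyProfile",
    "cwm_lambda",
    "estimate_cwm",
    "estimate_dq",
    "privacy_profile",
    "relative_risk_direction",
]

BOTH_NONE = "both_none"
EXACTLY_ONE = "exactly_one"


@dataclass(frozen=True)
class CwmDesign:
    """A crosswise design: innocuous-statement prevalence and its provenance."""

    p: float
    source: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0,1]")

    def _require_informative(self):
        if self.p == 0.5:
            raise ValueError("estimator undefined at p = 0.5 (no information)")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence point estimate with its standard error."""

    pi_hat: float
    se: float
    n: int
    method: str  # "closed_form" | "ml"
    out_of_range: bool = False
    degenerate: bool = False

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (self.pi_hat - z * self.se, self.pi_hat + z * self.se)


@dataclass(frozen=True)
class PrivacyProfile:
    """Conditional probabilities of being identified as a carrier given the
    chosen CWM answer option (Bayes)."""

    pr_carrier_given_both_none: float
    pr_carrier_given_one: float
    less_risky_option: str | None
    symmetric: bool


def cwm_lambda(pi: float, p: float) -> float:
    """Model-implied probability of the "both/none" answer:
    lambda = pi*p + (1-pi)*(1-p) = 1 - p + pi*(2p - 1)."""
    return 1.0 - p + pi * (2.0 * p - 1.0)


def estimate_cwm(lambda_hat: float, n: int, design: CwmDesign) -> PrevalenceEstimate:
    """Closed-form CWM prevalence estimate from the observed "both/none"
    proportion.  Out-of-[0,1] estimates are returned unclipped and flagged."""
    design._require_informative()
    if not 0.0 <= lambda_hat <= 1.0:
        raise ValueError(f"lambda_hat={lambda_hat} outside [0,1]")
    if n <= 0:
        raise ValueError("group size must be positive")
    denom = 2.0 * design.p - 1.0
    pi_hat = (lambda_hat + design.p - 1.0) / denom
    se = math.sqrt(lambda_hat * (1.0 - lambda_hat) / n) / abs(denom)
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        n=n,
        method="closed_form",
        out_of_range=not (0.0 <= pi_hat <= 1.0),
        degenerate=lambda_hat in (0.0, 1.0),
    )


def estimate_dq(k_true: int, n: int) -> PrevalenceEstimate:
    """Binomial proportion estimate for a direct question."""
    if n <= 0:
        raise ValueError("group size must be positive")
    if not 0 <= k_true <= n:
        raise ValueError(f"count {k_true} outside [0, {n}]")
    pi_hat = k_true / n
    se = math.sqrt(pi_hat * (1.0 - pi_hat) / n)
    return PrevalenceEstimate(
        pi_hat=pi_hat,
        se=se,
        n=n,
        method="closed_form",
        degenerate=k_true in (0, n),
    )


def privacy_profile(
    pi: float, design: CwmDesign, lambda_: float | None = None
) -> PrivacyProfile:
    """Posterior probability of carrying the sensitive attribute given each
    CWM answer option.

    When ``lambda_`` is not supplied it is derived from the model identity
    ``lambda = 1 - p + pi (2p - 1)``.  The design is *symmetric* when both
    conditional probabilities lie strictly inside (0, 1): no answer option
    unambiguously reveals (non-)carrier status.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError("privacy profile requires 0 < pi < 1")
    p = design.p
    if not 0.0 < p < 1.0:
        raise ValueError("privacy profile requires 0 < p < 1")
    lam = cwm_lambda(pi, p) if lambda_ is None else lambda_
    if lam in (0.0, 1.0):
        raise ValueError("lambda in {0,1}: conditional probabilities undefined")
    pr1 = pi * p / lam
    pr2 = pi * (1.0 - p) / (1.0 - lam)
    less_risky = None if p == 0.5 else (BOTH_NONE if p < 0.5 else EXACTLY_ONE)
    return PrivacyProfile(
        pr_carrier_given_both_none=pr1,
        pr_carrier_given_one=pr2,
        less_risky_option=less_risky,
        symmetric=(0.0 < pr1 < 1.0) and (0.0 < pr2 < 1.0),
    )


def relative_risk_direction(design: CwmDesign) -> str:
    """The answer option with the lower risk of being identified as a
    carrier: "both/none" for p < .5 (since p < 1-p), "exactly one" for
    p > .5."""
    design._require_informative()
    return BOTH_NONE if design.p < 0.5 else EXACTLY_ONE
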