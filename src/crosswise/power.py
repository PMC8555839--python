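"""Design and power computations for faking studies.

Exact noncentral-t and noncentral-F computations (the distributions G*Power
uses) for two-sample t-tests and fixed-effects ANOVA, a normal-approximation
power for detecting a nonzero prevalence under either questioning design,
and variance-based allocation guidance for splitting a sample between
crosswise-model and direct-question arms.

Conventions: Cohen's d is the standardized mean difference; the t-test
noncentrality is ``d / sqrt(1/n1 + 1/n2)``; Cohen's f gives the ANOVA
noncentrality ``f^2 * N``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from .design import CwmDesign, cwm_lambda

__all__ = [
    "posthoc_power_t",
    "mdes_two_sample_t",
    "power_anova_fixed",
    "mdes_anova_fixed",
    "power_prevalence_gt_zero",
    "allocation_ratio",
]


def _check_t_args(n1: int, n2: int, alpha: float, tails: int) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be at least 2 per group")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")


def posthoc_power_t(
    d: float, n1: int, n2: int, alpha: float = 0.05, tails: int = 2
) -> float:
    """Power of a two-sample t-test for effect size ``d`` (exact noncentral t).

    The rejection region uses the central-t critical value; power is the
    noncentral-t probability beyond it (both tails for ``tails=2``).
    """
    _check_t_args(n1, n2, alpha, tails)
    if d < 0:
        raise ValueError("d must be nonnegative")
    df = n1 + n2 - 2
    ncp = d / math.sqrt(1.0 / n1 + 1.0 / n2)
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def mdes_two_sample_t(
    n1: int,
    n2: int,
    alpha: float = 0.05,
    tails: int = 2,
    target_power: float = 0.80,
) -> float:
    """Minimum detectable effect size (sensitivity analysis): the smallest
    Cohen's d reaching ``target_power``, solved by root-finding to 1e-6."""
    _check_t_args(n1, n2, alpha, tails)
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0,1)")
    base = posthoc_power_t(0.0, n1, n2, alpha, tails)
    if target_power <= base:
        return 0.0
    hi = 0.5
    while posthoc_power_t(hi, n1, n2, alpha, tails) < target_power:
        hi *= 2.0
        if hi > 100:
            raise ValueError("target power unattainable")
    return float(
        optimize.brentq(
            lambda d: posthoc_power_t(d, n1, n2, alpha, tails) - target_power,
            0.0,
            hi,
            xtol=1e-6,
        )
    )


def power_anova_fixed(
    f: float, n_total: int, n_groups: int, df_num: int, alpha: float = 0.05
) -> float:
    """Power of a fixed-effects ANOVA F-test for Cohen's f, exact
    noncentral F with ncp = f^2 * N and df = (df_num, N - n_groups)."""
    if n_total <= n_groups:
        raise ValueError("n_total must exceed the number of groups")
    if f < 0:
        raise ValueError("f must be nonnegative")
    df_den = n_total - n_groups
    ncp = f * f * n_total
    fcrit = stats.f.ppf(1.0 - alpha, df_num, df_den)
    if ncp == 0.0:  # scipy's ncf is unreliable at zero noncentrality
        return float(alpha)
    return float(stats.ncf.sf(fcrit, df_num, df_den, ncp))


def mdes_anova_fixed(
    n_total: int,
    n_groups: int,
    df_num: int,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> float:
    """Smallest Cohen's f reaching ``target_power`` in the fixed-effects
    ANOVA F-test."""
    hi = 0.1
    while power_anova_fixed(hi, n_total, n_groups, df_num, alpha) < target_power:
        hi *= 2.0
        if hi > 100:
            raise ValueError("target power unattainable")
    return float(
        optimize.brentq(
            lambda f: power_anova_fixed(f, n_total, n_groups, df_num, alpha)
            - target_power,
            0.0,
            hi,
            xtol=1e-6,
        )
    )


def power_prevalence_gt_zero(
    pi: float,
    n: int,
    alpha: float = 0.05,
    design: "str | CwmDesign" = "DQ",
    method: str = "normal",
    n_sim: int = 10_000,
    rng=None,
) -> float:
    """Power of the one-sided Wald test of pi > 0 at true prevalence ``pi``.

    ``design`` is "DQ" for a direct question or a :class:`CwmDesign`; the
    design-specific standard error (binomial, or the crosswise delta-method
    SE) enters the test statistic.  ``method="normal"`` determines the exact
    rejection region of the Wald statistic over the answer counts and
    evaluates its probability by a continuity-corrected normal approximation
    to the binomial; ``method="montecarlo"`` simulates the rejection rate of
    the same test.
    """
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must be in [0,1)")
    if n < 2:
        raise ValueError("n too small")
    z = stats.norm.ppf(1.0 - alpha)
    if pi == 0.0:
        return float(alpha)

    is_dq = design in ("DQ", "dq", None)
    if is_dq:
        answer_prob = pi
    else:
        if isinstance(design, str):
            raise ValueError(f"unknown design {design!r}; pass 'DQ' or a CwmDesign")
        design._require_informative()
        answer_prob = cwm_lambda(pi, design.p)

    def wald_stat(k: np.ndarray) -> np.ndarray:
        prop = k / n
        if is_dq:
            pi_hat = prop
            se = np.sqrt(np.maximum(prop * (1 - prop), 1e-12) / n)
        else:
            pi_hat = (prop + design.p - 1.0) / (2.0 * design.p - 1.0)
            se = np.sqrt(np.maximum(prop * (1 - prop), 1e-12) / n) / abs(
                2.0 * design.p - 1.0
            )
        return pi_hat / se

    if method == "normal":
        ks = np.arange(n + 1)
        reject = wald_stat(ks) > z  # contiguous region (statistic monotone in k)
        if not reject.any():
            return 0.0
        lo, hi = ks[reject][0], ks[reject][-1]
        mean, sd = n * answer_prob, math.sqrt(n * answer_prob * (1 - answer_prob))
        return float(
            stats.norm.cdf((hi + 0.5 - mean) / sd)
            - stats.norm.cdf((lo - 0.5 - mean) / sd)
        )
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(rng)
    k = rng.binomial(n, answer_prob, size=n_sim)
    return float(np.mean(wald_stat(k) > z))


def allocation_ratio(pi_expected: float, p: float) -> float:
    """Variance-based (Neyman-style) CWM:DQ allocation ratio.

    Per-respondent estimator variances are ``lambda(1-lambda)/(2p-1)^2`` for
    the crosswise design and ``pi(1-pi)`` for the direct question; the
    optimal allocation assigns respondents proportionally to the square root
    of the variance ratio.  Published practice rounds this to a 2:1
    convention.
    """
    if not 0.0 < pi_expected < 1.0:
        raise ValueError("pi_expected must be in (0,1)")
    if p == 0.5:
        raise ValueError("p=0.5: crosswise variance infinite")
    lam = cwm_lambda(pi_expected, p)
    var_cwm = lam * (1.0 - lam) / (2.0 * p - 1.0) ** 2
    var_dq = pi_expected * (1.0 - pi_expected)
    if var_dq <= 0:
        raise ValueError("degenerate direct-question variance")
    return math.sqrt(var_cwm / var_dq)
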