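"""End-to-end analysis of a 2x2 faking study (instruction x questioning
technique).

``FakingStudy`` binds a four-condition count table (direct question and
crosswise model, each under honest and fake-good instructions) to the MPT
machinery and, on ``fit()``, produces a ``FakingStudyResults`` holding

* the four ML prevalence estimates with standard errors,
* the shrinkage ratios ``alpha = pi_fake / pi_honest`` per technique, with
  SEs, from the order-constraint reparameterization,
* five df=1 likelihood-ratio comparisons: the instruction effect within each
  technique, the technique effect within each instruction, and the
  instruction-by-technique interaction (equality of the two shrinkage
  ratios),
* Likert-item analyses (2x2 Type III ANOVA and Bonferroni-corrected pairwise
  t-tests) when respondent-level records are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CwmDesign, PrevalenceEstimate, estimate_cwm, estimate_dq
from .mpt import (
    Branch,
    CountTable,
    LRComparison,
    MPTModel,
    MPTResults,
    Parameter,
    TreeModel,
    compare_models,
    cwm_tree,
    dq_tree,
)

__all__ = [
    "CONDITIONS",
    "four_condition_model",
    "FakingStudy",
    "FakingStudyResults",
    "ShrinkageEstimate",
    "run_likert_analyses",
]

REPORT_SCHEMA_VERSION = "1.0"

#: canonical condition labels, (technique, instruction) -> tree id
CONDITIONS = {
    ("DQ", "honest"): "dq_honest",
    ("DQ", "fake_good"): "dq_fake_good",
    ("CWM", "honest"): "cwm_honest",
    ("CWM", "fake_good"): "cwm_fake_good",
}

_PI = {
    "dq_honest": "pi_dq_honest",
    "dq_fake_good": "pi_dq_fake",
    "cwm_honest": "pi_cwm_honest",
    "cwm_fake_good": "pi_cwm_fake",
}

#: the four predeclared pairwise Likert contrasts (Bonferroni factor 4)
LIKERT_PAIRS = [
    ("dq_honest", "dq_fake_good"),
    ("cwm_honest", "cwm_fake_good"),
    ("dq_honest", "cwm_honest"),
    ("dq_fake_good", "cwm_fake_good"),
]

LIKERT_ITEMS = ["sensitivity", "confidentiality", "ease"]


def four_condition_model(p: float = 0.158) -> TreeModel:
    """The unrestricted four-tree model: one prevalence parameter per
    condition, randomization probability fixed to ``p`` in the CWM trees."""
    branches: list[Branch] = []
    branches += dq_tree("dq_honest", "pi_dq_honest")
    branches += dq_tree("dq_fake_good", "pi_dq_fake")
    branches += cwm_tree("cwm_honest", "pi_cwm_honest", "p")
    branches += cwm_tree("cwm_fake_good", "pi_cwm_fake", "p")
    params = [
        Parameter("pi_dq_honest"),
        Parameter("pi_dq_fake"),
        Parameter("pi_cwm_honest"),
        Parameter("pi_cwm_fake"),
        Parameter("p", "constant", p),
    ]
    return TreeModel(branches, params)


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Shrinkage ratio alpha = pi_fake / pi_honest for one technique."""

    alpha_hat: float
    se: float
    order_constraint_satisfied: bool  # alpha <= 1
    at_upper_bound: bool = False      # capped at the [0, 2] reporting bound


@dataclass
class FakingStudyResults:
    """Fitted results of a 2x2 faking study."""

    study: "FakingStudy"
    estimates: dict[str, PrevalenceEstimate]
    closed_form: dict[str, PrevalenceEstimate]
    alpha: dict[str, ShrinkageEstimate]
    comparisons: list[LRComparison]
    differences: dict[str, float]
    baseline_fit: MPTResults = field(repr=False, default=None)

    # ------------------------------------------------------------- reporting
    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "p": self.study.design.p,
            "estimates": {
                cond: {
                    "pi_hat": e.pi_hat,
                    "se": e.se,
                    "n": e.n,
                    "method": e.method,
                }
                for cond, e in self.estimates.items()
            },
            "shrinkage": {
                tech: {
                    "alpha_hat": a.alpha_hat,
                    "se": a.se,
                    "order_constraint_satisfied": a.order_constraint_satisfied,
                    "at_upper_bound": a.at_upper_bound,
                }
                for tech, a in self.alpha.items()
            },
            "comparisons": [
                {
                    "restriction": c.restriction,
                    "difference": self.differences.get(c.restriction),
                    "delta_g_squared": c.delta_g_squared,
                    "df": c.df,
                    "p_value": c.p_value,
                }
                for c in self.comparisons
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        """Aligned-text report mirroring the published table layout:
        percentages and G² to two decimals."""
        e = self.estimates

        def pct(cond):
            est = e[cond]
            return f"{100 * est.pi_hat:.2f} ({100 * est.se:.2f})"

        a = self.alpha

        def apct(tech):
            s = a[tech]
            return f"{100 * s.alpha_hat:.2f} ({100 * s.se:.2f})"

        lines = [
            "Prevalence estimates (SE), percent",
            f"{'':<14}{'DQ':>16}{'CWM':>16}",
            f"{'honest':<14}{pct('dq_honest'):>16}{pct('cwm_honest'):>16}",
            f"{'fake good':<14}{pct('dq_fake_good'):>16}{pct('cwm_fake_good'):>16}",
            "",
            "Shrinkage alpha = pi_fake / pi_honest (SE), percent",
            f"{'':<14}{apct('DQ'):>16}{apct('CWM'):>16}",
            "",
            "Model comparisons (df = 1)",
            f"{'restriction':<34}{'|diff|':>8}{'dG2':>8}{'p':>9}",
        ]
        for c in self.comparisons:
            d = self.differences.get(c.restriction)
            d_txt = f"{100 * d:.2f}" if d is not None else "--"
            p_txt = "<.001" if c.p_value < 0.001 else f"{c.p_value:.3f}"
            lines.append(
                f"{c.restriction:<34}{d_txt:>8}{c.delta_g_squared:>8.2f}{p_txt:>9}"
            )
        return "\n".join(lines)

    def render(self, format: str = "text") -> str:
        """Deterministic report rendering ("text" or "json")."""
        if not self.comparisons:
            raise ValueError("cannot render a report without model comparisons")
        if format == "json":
            return self.to_json()
        if format == "text":
            return self.summary()
        raise ValueError(f"unknown format {format!r}")

    def plot_estimates(self, ax=None):
        """Point estimates with 95% Wald intervals, per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        order = ["dq_honest", "dq_fake_good", "cwm_honest", "cwm_fake_good"]
        x = np.arange(len(order))
        y = [100 * self.estimates[c].pi_hat for c in order]
        err = [100 * 1.959964 * self.estimates[c].se for c in order]
        ax.errorbar(x, y, yerr=err, fmt="o", capsize=4)
        ax.set_xticks(x)
        ax.set_xticklabels(order, rotation=20)
        ax.set_ylabel("prevalence estimate (%)")
        return ax


class FakingStudy:
    """A 2x2 faking study bound to observed counts.

    Parameters
    ----------
    counts
        CountTable with the four conditions ``dq_honest``, ``dq_fake_good``,
        ``cwm_honest``, ``cwm_fake_good`` (or metadata identifying
        technique/instruction).
    p
        Randomization probability of the crosswise design.
    """

    def __init__(self, counts: CountTable, p: float = 0.158):
        self.design = CwmDesign(p)
        self.counts = self._canonicalize(counts)
        self.tree_model = four_condition_model(p)

    @staticmethod
    def _canonicalize(counts: CountTable) -> CountTable:
        present = set(counts.trees)
        expected = set(CONDITIONS.values())
        if present == expected:
            return counts
        # map via metadata
        mapping = {}
        for tree in counts.trees:
            meta = counts.meta.get(tree, {})
            key = (meta.get("technique"), meta.get("instruction"))
            if key in CONDITIONS:
                mapping[tree] = CONDITIONS[key]
        if set(mapping.values()) != expected:
            missing = expected - set(mapping.values()) - present
            raise ValueError(f"count table is missing conditions: {sorted(missing)}")
        return CountTable(
            {mapping[t]: counts.counts[t] for t in counts.trees},
            meta={mapping[t]: counts.meta.get(t, {}) for t in counts.trees},
        )

    @classmethod
    def from_csv(cls, path, p: float = 0.158) -> "FakingStudy":
        return cls(CountTable.from_csv(path), p=p)

    # ------------------------------------------------------------ closed form
    def closed_form_estimates(self) -> dict[str, PrevalenceEstimate]:
        c = self.counts
        return {
            "dq_honest": estimate_dq(c.counts["dq_honest"].get("true", 0), c.n("dq_honest")),
            "dq_fake_good": estimate_dq(
                c.counts["dq_fake_good"].get("true", 0), c.n("dq_fake_good")
            ),
            "cwm_honest": estimate_cwm(
                c.counts["cwm_honest"].get("both_none", 0) / c.n("cwm_honest"),
                c.n("cwm_honest"),
                self.design,
            ),
            "cwm_fake_good": estimate_cwm(
                c.counts["cwm_fake_good"].get("both_none", 0) / c.n("cwm_fake_good"),
                c.n("cwm_fake_good"),
                self.design,
            ),
        }

    # ----------------------------------------------------------------- fitting
    def fit(self, tol: float = 1e-10, max_iter: int = 10_000) -> FakingStudyResults:
        closed = self.closed_form_estimates()
        init = {
            _PI[cond]: float(np.clip(est.pi_hat, 0.01, 0.99))
            for cond, est in closed.items()
        }
        fit_kw = dict(tol=tol, max_iter=max_iter)
        base = MPTModel(self.tree_model, self.counts).fit(init=init, **fit_kw)
        if not base.converged:
            raise RuntimeError("baseline model fit did not converge")

        estimates = {
            cond: PrevalenceEstimate(
                pi_hat=float(base.params[_PI[cond]]),
                se=float(base.bse[_PI[cond]]),
                n=self.counts.n(cond),
                method="ml",
            )
            for cond in CONDITIONS.values()
        }

        # shrinkage reparameterization, per technique
        alpha: dict[str, ShrinkageEstimate] = {}
        shrink_model, shrink_init, directions = self._shrinkage_model(base)
        shrink_fit = MPTModel(shrink_model, self.counts).fit(init=shrink_init, **fit_kw)
        for tech in ("DQ", "CWM"):
            alpha[tech] = self._alpha_from_fit(shrink_fit, tech, directions[tech])

        # five df=1 comparisons against the unrestricted / both-alpha baselines
        comparisons: list[LRComparison] = []
        differences: dict[str, float] = {}

        def equality(label, a, b):
            restricted = self.tree_model.with_equal([_PI[a], _PI[b]])
            pooled = (
                estimates[a].pi_hat * self.counts.n(a)
                + estimates[b].pi_hat * self.counts.n(b)
            ) / (self.counts.n(a) + self.counts.n(b))
            r_init = {n: v for n, v in init.items() if n != _PI[b]}
            r_init[_PI[a]] = float(np.clip(pooled, 0.01, 0.99))
            r_fit = MPTModel(restricted, self.counts).fit(init=r_init, **fit_kw)
            comp = compare_models(base, r_fit, label)
            comparisons.append(comp)
            differences[label] = abs(estimates[a].pi_hat - estimates[b].pi_hat)

        equality("pi_dq_honest = pi_dq_fake", "dq_honest", "dq_fake_good")
        equality("pi_cwm_honest = pi_cwm_fake", "cwm_honest", "cwm_fake_good")
        equality("pi_dq_honest = pi_cwm_honest", "dq_honest", "cwm_honest")
        equality("pi_dq_fake = pi_cwm_fake", "dq_fake_good", "cwm_fake_good")

        label = "alpha_dq = alpha_cwm"
        r_fit = self._fit_equal_alpha(shrink_fit, **fit_kw)
        comparisons.append(compare_models(shrink_fit, r_fit, label))
        differences[label] = abs(alpha["DQ"].alpha_hat - alpha["CWM"].alpha_hat)

        return FakingStudyResults(
            study=self,
            estimates=estimates,
            closed_form=closed,
            alpha=alpha,
            comparisons=comparisons,
            differences=differences,
            baseline_fit=base,
        )

    # ----------------------------------------------------- shrinkage helpers
    def _shrinkage_model(self, base: MPTResults):
        """Reparameterize pi_fake = alpha * pi_honest per technique.

        When the unrestricted ratio exceeds 1 the roles are mirrored
        (pi_honest = beta * pi_fake) so the EM parameter stays in [0, 1];
        the reported alpha is then 1/beta, capped at the [0, 2] bound.
        """
        model = self.tree_model
        directions: dict[str, str] = {}
        init: dict[str, float] = {}
        for tech, honest, fake in (
            ("DQ", "pi_dq_honest", "pi_dq_fake"),
            ("CWM", "pi_cwm_honest", "pi_cwm_fake"),
        ):
            ratio = base.params[fake] / max(base.params[honest], 1e-12)
            # init at the exact MLE of the reparameterization (invariance of
            # the ML estimate): EM then only needs to confirm convergence
            if ratio <= 1.0:
                directions[tech] = "forward"
                model = model.reparameterize_shrinkage(honest, fake, f"alpha_{tech.lower()}")
                init[honest] = float(base.params[honest])
                init[f"alpha_{tech.lower()}"] = float(np.clip(ratio, 1e-6, 1 - 1e-9))
            else:
                directions[tech] = "reverse"
                model = model.reparameterize_shrinkage(fake, honest, f"beta_{tech.lower()}")
                init[fake] = float(base.params[fake])
                init[f"beta_{tech.lower()}"] = float(np.clip(1.0 / ratio, 1e-6, 1 - 1e-9))
        return model, init, directions

    @staticmethod
    def _alpha_from_fit(fit: MPTResults, tech: str, direction: str) -> ShrinkageEstimate:
        if direction == "forward":
            name = f"alpha_{tech.lower()}"
            a = float(fit.params[name])
            se = float(fit.bse[name])
            return ShrinkageEstimate(a, se, order_constraint_satisfied=a <= 1.0)
        name = f"beta_{tech.lower()}"
        b = float(fit.params[name])
        a = 1.0 / b
        se = float(fit.bse[name]) / b**2  # delta method for 1/beta
        capped = a > 2.0
        return ShrinkageEstimate(
            min(a, 2.0), se, order_constraint_satisfied=False, at_upper_bound=capped
        )

    def _fit_equal_alpha(self, shrink_fit: MPTResults, **fit_kw) -> MPTResults:
        """Restricted model with a single shrinkage ratio shared across
        techniques; tried in both orientations, better likelihood kept."""
        candidates = []
        for honest_first in (True, False):
            if honest_first:
                pairs = (("pi_dq_honest", "pi_dq_fake"), ("pi_cwm_honest", "pi_cwm_fake"))
            else:
                pairs = (("pi_dq_fake", "pi_dq_honest"), ("pi_cwm_fake", "pi_cwm_honest"))
            model = self.tree_model
            names = []
            for i, (keep, replace) in enumerate(pairs):
                model = model.reparameterize_shrinkage(keep, replace, f"ratio_{i}")
                names.append(f"ratio_{i}")
            model = model.with_equal(names, to="ratio")
            init = {}
            ratios = []
            for keep, replace in pairs:
                kept = float(np.clip(self._base_param(shrink_fit, keep), 0.01, 0.99))
                init[keep] = kept
                ratios.append(
                    float(np.clip(self._base_param(shrink_fit, replace) / kept, 0.01, 0.99))
                )
            init["ratio"] = float(np.mean(ratios))
            try:
                candidates.append(MPTModel(model, self.counts).fit(init=init, **fit_kw))
            except RuntimeError:
                continue
        converged = [c for c in candidates if c.converged]
        if not converged:
            raise RuntimeError("equal-shrinkage restricted fit failed")
        return max(converged, key=lambda f: f.llf)

    def _base_param(self, shrink_fit: MPTResults, name: str) -> float:
        """Recover an original-parameterization prevalence from the
        shrinkage fit (pi_fake = alpha * pi_honest or mirrored)."""
        p = shrink_fit.params
        if name in p.index:
            return float(p[name])
        tech = "dq" if "dq" in name else "cwm"
        if f"alpha_{tech}" in p.index:
            honest = f"pi_{tech}_honest"
            return float(p[honest] * p[f"alpha_{tech}"])
        fake = f"pi_{tech}_fake"
        return float(p[fake] * p[f"beta_{tech}"])


# ---------------------------------------------------------------------------
# Likert analyses


def run_likert_analyses(
    records: pd.DataFrame,
    items: list[str] | None = None,
    equal_var: bool = True,
) -> dict[str, dict[str, pd.DataFrame]]:
    """2x2 ANOVAs and Bonferroni-corrected pairwise t-tests per Likert item.

    Parameters
    ----------
    records
        Respondent-level data with ``technique``, ``instruction`` and
        ``likert_<item>`` columns.
    items
        Item names (default: sensitivity, confidentiality, ease).
    equal_var
        Student (pooled-variance) t-tests by default; False for Welch.

    Returns
    -------
    dict mapping item -> {"anova": DataFrame, "pairwise": DataFrame}.  The
    ANOVA uses Type III sums of squares with sum-to-zero contrasts (suitable
    for the unbalanced 2x2 design); pairwise p-values are multiplied by 4
    and capped at 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    items = items or LIKERT_ITEMS
    df = records.copy()
    df["condition"] = (
        df["technique"].str.lower() + "_" + df["instruction"].astype(str)
    )
    cell_sizes = df.groupby(["technique", "instruction"]).size()
    if (cell_sizes < 2).any() or len(cell_sizes) < 4:
        raise ValueError("every cell of the 2x2 design needs at least 2 respondents")

    out: dict[str, dict[str, pd.DataFrame]] = {}
    for item in items:
        col = f"likert_{item}"
        if col not in df.columns:
            raise KeyError(f"records lack column {col!r}")
        work = df[["condition", "technique", "instruction", col]].dropna()
        model = smf.ols(
            f"{col} ~ C(instruction, Sum) * C(technique, Sum)", data=work
        ).fit()
        anova = sm.stats.anova_lm(model, typ=3)

        rows = []
        for a, b in LIKERT_PAIRS:
            xa = work.loc[work["condition"] == a, col]
            xb = work.loc[work["condition"] == b, col]
            t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            sd = np.sqrt(
                (
                    (len(xa) - 1) * xa.var(ddof=1)
                    + (len(xb) - 1) * xb.var(ddof=1)
                )
                / (len(xa) + len(xb) - 2)
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "cohens_d": (xa.mean() - xb.mean()) / sd if sd > 0 else np.nan,
                    "t": t,
                    "df": len(xa) + len(xb) - 2,
                    "p_raw": p,
                    "p_bonferroni": min(4 * p, 1.0),
                }
            )
        out[item] = {"anova": anova, "pairwise": pd.DataFrame(rows)}
    return out
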