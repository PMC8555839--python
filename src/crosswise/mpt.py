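"""Binary multinomial processing tree (MPT) models with EM maximum likelihood.

An MPT model expresses the probability of each observable answer category as a
sum of branch probabilities, where every branch is a product of parameters
``theta`` or complements ``1 - theta``.  Separate trees describe separate
experimental conditions; parameters may be shared across trees, fixed to known
constants (e.g. a randomization probability), tied by equality restrictions,
or replaced by products of other parameters (order-constraint
reparameterization).  Fitting maximises the product-multinomial likelihood of
observed category counts by expectation-maximization, and nested models are
compared through the likelihood-ratio statistic G².
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Factor",
    "Branch",
    "Parameter",
    "TreeModel",
    "CountTable",
    "MPTModel",
    "MPTResults",
    "LRComparison",
    "compare_models",
    "dq_tree",
    "cwm_tree",
]

#: clip bound keeping E-step weights defined near the boundary of [0, 1]
BOUND_EPS = 1e-8


@dataclass(frozen=True)
class Factor:
    """One multiplicative term of a branch: ``theta`` or ``1 - theta``."""

    name: str
    complement: bool = False

    def to_tuple(self) -> tuple[str, str]:
        return (self.name, "complement" if self.complement else "direct")

    @classmethod
    def from_spec(cls, spec) -> "Factor":
        if isinstance(spec, Factor):
            return spec
        name, orientation = spec
        if orientation not in ("direct", "complement"):
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(name, orientation == "complement")


@dataclass(frozen=True)
class Branch:
    """A root-to-leaf path of one tree, terminating in an answer category."""

    tree: str
    category: str
    factors: tuple[Factor, ...]

    def probability(self, values: Mapping[str, float]) -> float:
        prob = 1.0
        for f in self.factors:
            theta = values[f.name]
            prob *= (1.0 - theta) if f.complement else theta
        return prob


@dataclass(frozen=True)
class Parameter:
    """A model parameter: free within bounds, or a known constant."""

    name: str
    role: str = "free"  # "free" | "constant"
    value: float | None = None
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.role not in ("free", "constant"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "constant":
            if self.value is None:
                raise ValueError(f"constant parameter {self.name!r} needs a value")
            if not 0.0 <= self.value <= 1.0:
                raise ValueError(f"constant {self.name!r}={self.value} outside [0,1]")
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bounds {self.bounds} must be a closed interval in [0,1]")


class TreeModel:
    """A set of binary processing trees over named parameters.

    Parameters
    ----------
    branches
        Branch objects; every (tree, category) cell may collect several
        branches, whose probabilities are summed.
    parameters
        Parameter declarations.  Every factor name must be declared.
    """

    def __init__(self, branches: Iterable[Branch], parameters: Iterable[Parameter]):
        self.branches: tuple[Branch, ...] = tuple(branches)
        self.parameters: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in self.parameters:
                raise ValueError(f"duplicate parameter {p.name!r}")
            self.parameters[p.name] = p
        for b in self.branches:
            for f in b.factors:
                if f.name not in self.parameters:
                    raise ValueError(f"branch references undeclared parameter {f.name!r}")
        # stable tree / category orderings by first appearance
        self.trees: tuple[str, ...] = tuple(dict.fromkeys(b.tree for b in self.branches))

    # ------------------------------------------------------------------ views
    def categories(self, tree: str) -> tuple[str, ...]:
        return tuple(dict.fromkeys(b.category for b in self.branches if b.tree == tree))

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n, p in self.parameters.items() if p.role == "free")

    @property
    def n_independent_categories(self) -> int:
        return sum(len(self.categories(t)) - 1 for t in self.trees)

    # ------------------------------------------------------------ evaluation
    def full_values(self, values: Mapping[str, float]) -> dict[str, float]:
        """Merge free-parameter values with declared constants; validate."""
        out: dict[str, float] = {}
        for name, p in self.parameters.items():
            if p.role == "constant":
                out[name] = p.value  # type: ignore[assignment]
            else:
                if name not in values:
                    raise KeyError(f"no value supplied for free parameter {name!r}")
                v = float(values[name])
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"value {v} for {name!r} outside [0,1]")
                lo, hi = p.bounds
                if v < lo - 1e-12 or v > hi + 1e-12:
                    raise ValueError(f"value {v} for {name!r} outside bounds {p.bounds}")
                out[name] = v
        unknown = set(values) - set(self.parameters)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return out

    def category_probabilities(
        self, values: Mapping[str, float]
    ) -> dict[str, dict[str, float]]:
        """Per-tree answer-category probability vectors (each sums to 1)."""
        vals = self.full_values(values)
        out: dict[str, dict[str, float]] = {
            t: {c: 0.0 for c in self.categories(t)} for t in self.trees
        }
        for b in self.branches:
            out[b.tree][b.category] += b.probability(vals)
        return out

    # --------------------------------------------------------- restrictions
    def with_constant(self, name: str, value: float) -> "TreeModel":
        """Fix a free parameter to a constant (a nested restriction)."""
        if name not in self.parameters:
            raise KeyError(name)
        params = [
            Parameter(name, "constant", value) if p.name == name else p
            for p in self.parameters.values()
        ]
        return TreeModel(self.branches, params)

    def with_equal(self, names: Sequence[str], to: str | None = None) -> "TreeModel":
        """Tie several free parameters to a single shared parameter."""
        names = list(names)
        for n in names:
            if n not in self.parameters:
                raise KeyError(n)
            if self.parameters[n].role != "free":
                raise ValueError(f"cannot tie constant parameter {n!r}")
        target = to or names[0]
        rename = {n: target for n in names}
        branches = [
            Branch(
                b.tree,
                b.category,
                tuple(Factor(rename.get(f.name, f.name), f.complement) for f in b.factors),
            )
            for b in self.branches
        ]
        bounds = self.parameters[names[0]].bounds
        params = [p for p in self.parameters.values() if p.name not in rename]
        params.append(Parameter(target, "free", bounds=bounds))
        return TreeModel(branches, params)

    def reparameterize_shrinkage(
        self, honest: str, fake: str, alpha_name: str
    ) -> "TreeModel":
        """Replace ``pi_fake`` by ``alpha * pi_honest`` (order constraint).

        Uses the exact binary-MPT rewrite ``1 - a*h = (1 - h) + h*(1 - a)`` so
        the result is again a product-of-parameters tree and EM applies with
        ``alpha`` in [0, 1].  Estimates of the original parameterization are
        recovered as ``pi_fake = alpha * pi_honest``.
        """
        for n in (honest, fake):
            if n not in self.parameters or self.parameters[n].role != "free":
                raise KeyError(f"model lacks free parameter {n!r}")
        branches: list[Branch] = []
        for b in self.branches:
            todo = [(b.factors, ())]  # (remaining factors, rewritten prefix)
            done: list[tuple[Factor, ...]] = []
            while todo:
                rest, prefix = todo.pop()
                for i, f in enumerate(rest):
                    if f.name == fake:
                        pre = prefix + rest[:i]
                        post = rest[i + 1 :]
                        if not f.complement:
                            # a*h
                            todo.append((post, pre + (Factor(honest), Factor(alpha_name))))
                        else:
                            # 1 - a*h = (1-h) + h*(1-a)
                            todo.append((post, pre + (Factor(honest, True),)))
                            todo.append(
                                (post, pre + (Factor(honest), Factor(alpha_name, True)))
                            )
                        break
                else:
                    done.append(prefix + rest)
            for factors in done:
                branches.append(Branch(b.tree, b.category, factors))
        params = [p for p in self.parameters.values() if p.name != fake]
        params.append(Parameter(alpha_name, "free"))
        return TreeModel(branches, params)

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": p.name,
                    "role": p.role,
                    **({"value": p.value} if p.role == "constant" else {}),
                    "bounds": list(p.bounds),
                }
                for p in self.parameters.values()
            ],
            "branches": [
                {
                    "tree": b.tree,
                    "category": b.category,
                    "factors": [list(f.to_tuple()) for f in b.factors],
                }
                for b in self.branches
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreeModel":
        params = [
            Parameter(
                q["name"],
                q.get("role", "free"),
                q.get("value"),
                tuple(q.get("bounds", (0.0, 1.0))),
            )
            for q in d["parameters"]
        ]
        branches = [
            Branch(
                q["tree"],
                q["category"],
                tuple(Factor.from_spec(f) for f in q["factors"]),
            )
            for q in d["branches"]
        ]
        return cls(branches, params)

    @classmethod
    def from_json(cls, path) -> "TreeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# standard tree builders


def dq_tree(tree: str, pi: str) -> list[Branch]:
    """Direct question: answer 'true' with probability pi, else 'false'."""
    return [
        Branch(tree, "true", (Factor(pi),)),
        Branch(tree, "false", (Factor(pi, True),)),
    ]


def cwm_tree(tree: str, pi: str, p: str = "p") -> list[Branch]:
    """Crosswise question: 'both_none' when carrier status and the innocuous
    statement coincide, 'exactly_one' otherwise."""
    return [
        Branch(tree, "both_none", (Factor(pi), Factor(p))),
        Branch(tree, "both_none", (Factor(pi, True), Factor(p, True))),
        Branch(tree, "exactly_one", (Factor(pi), Factor(p, True))),
        Branch(tree, "exactly_one", (Factor(pi, True), Factor(p))),
    ]


# ---------------------------------------------------------------------------
# data container


class CountTable:
    """Observed answer frequencies per tree (experimental condition)."""

    def __init__(self, counts: Mapping[str, Mapping[str, int]],
                 meta: Mapping[str, Mapping[str, str]] | None = None):
        self.counts: dict[str, dict[str, int]] = {}
        for tree, cats in counts.items():
            row = {}
            for cat, k in cats.items():
                k = int(k)
                if k < 0:
                    raise ValueError(f"negative count for {tree}/{cat}")
                row[cat] = k
            if sum(row.values()) <= 0:
                raise ValueError(f"tree {tree!r} has group size 0")
            self.counts[tree] = row
        self.meta = {t: dict(m) for t, m in (meta or {}).items()}

    @property
    def trees(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def n(self, tree: str) -> int:
        return sum(self.counts[tree].values())

    def categories(self, tree: str) -> tuple[str, ...]:
        return tuple(self.counts[tree])

    # ------------------------------------------------------------------- IO
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        """Columns: condition, technique, instruction, category, count[, n]."""
        counts: dict[str, dict[str, int]] = {}
        meta: dict[str, dict[str, str]] = {}
        for _, row in df.iterrows():
            cond = str(row["condition"])
            counts.setdefault(cond, {})[str(row["category"])] = int(row["count"])
            meta.setdefault(cond, {})
            for col in ("technique", "instruction"):
                if col in df.columns:
                    meta[cond][col] = str(row[col])
        table = cls(counts, meta)
        if "n" in df.columns:
            for cond, grp in df.groupby("condition"):
                n_declared = int(grp["n"].iloc[0])
                if table.n(str(cond)) != n_declared:
                    raise ValueError(
                        f"counts for {cond!r} sum to {table.n(str(cond))}, "
                        f"declared n={n_declared}"
                    )
        return table

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tree, cats in self.counts.items():
            for cat, k in cats.items():
                row = {"condition": tree}
                row.update(self.meta.get(tree, {}))
                row.update({"category": cat, "count": k, "n": self.n(tree)})
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __repr__(self) -> str:
        inner = ", ".join(f"{t}: n={self.n(t)}" for t in self.trees)
        return f"CountTable({inner})"


# ---------------------------------------------------------------------------
# compiled likelihood


class _Compiled:
    """Array form of (model, data) for fast EM and likelihood evaluation."""

    def __init__(self, model: TreeModel, data: CountTable):
        self.free = list(model.free_names)
        cells: list[tuple[str, str]] = []
        counts: list[int] = []
        for tree in model.trees:
            if tree not in data.counts:
                raise ValueError(f"no data for tree {tree!r}")
            model_cats = set(model.categories(tree))
            data_cats = set(data.categories(tree))
            if not data_cats <= model_cats:
                raise ValueError(
                    f"data categories {sorted(data_cats - model_cats)} not in model "
                    f"tree {tree!r}"
                )
            for cat in model.categories(tree):
                cells.append((tree, cat))
                counts.append(data.counts[tree].get(cat, 0))
        extra = set(data.trees) - set(model.trees)
        if extra:
            raise ValueError(f"data contains unknown trees {sorted(extra)}")
        self.cells = cells
        self.counts = np.asarray(counts, dtype=float)
        cell_index = {cell: i for i, cell in enumerate(cells)}
        k = len(self.free)
        fidx = {n: i for i, n in enumerate(self.free)}
        nb = len(model.branches)
        self.D = np.zeros((nb, k))  # direct occurrences of free params
        self.C = np.zeros((nb, k))  # complement occurrences
        self.const = np.ones(nb)    # product over constant factors
        self.cell_of = np.zeros(nb, dtype=int)
        for j, b in enumerate(model.branches):
            self.cell_of[j] = cell_index[(b.tree, b.category)]
            for f in b.factors:
                p = model.parameters[f.name]
                if p.role == "constant":
                    self.const[j] *= (1.0 - p.value) if f.complement else p.value
                elif f.complement:
                    self.C[j, fidx[f.name]] += 1
                else:
                    self.D[j, fidx[f.name]] += 1
        # saturated log-likelihood (per-tree multinomial MLE at observed freqs)
        ns = np.array([data.n(t) for t, _ in cells], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.counts > 0, self.counts * np.log(self.counts / ns), 0.0)
        self.ll_saturated = float(terms.sum())
        self.n_cells = len(cells)

    def branch_probs(self, theta: np.ndarray) -> np.ndarray:
        t = np.clip(theta, BOUND_EPS, 1.0 - BOUND_EPS)
        return self.const * np.exp(self.D @ np.log(t) + self.C @ np.log1p(-t))

    def cell_probs(self, theta: np.ndarray) -> np.ndarray:
        bp = self.branch_probs(theta)
        P = np.zeros(self.n_cells)
        np.add.at(P, self.cell_of, bp)
        return P

    def loglik(self, theta: np.ndarray) -> float:
        P = np.maximum(self.cell_probs(theta), 1e-300)
        return float(self.counts @ np.log(P))

    def em_step(self, theta: np.ndarray) -> np.ndarray:
        bp = self.branch_probs(theta)
        P = np.zeros(self.n_cells)
        np.add.at(P, self.cell_of, bp)
        P = np.maximum(P, 1e-300)
        w = self.counts[self.cell_of] * bp / P[self.cell_of]
        a = w @ self.D
        c = w @ self.C
        tot = a + c
        new = np.where(tot > 0, a / np.maximum(tot, 1e-300), theta)
        return np.clip(new, BOUND_EPS, 1.0 - BOUND_EPS)


# ---------------------------------------------------------------------------
# results


@dataclass
class MPTResults:
    """Maximum-likelihood fit of a TreeModel to a CountTable."""

    model: "MPTModel"
    params: pd.Series
    bse: pd.Series
    llf: float
    g_squared: float
    df_resid: int
    converged: bool
    n_iter: int
    at_boundary: pd.Series
    se_flags: dict[str, str] = field(default_factory=dict)

    @property
    def p_value_fit(self) -> float:
        """Goodness-of-fit p for G² against the saturated model."""
        if self.df_resid <= 0:
            return 1.0
        return float(stats.chi2.sf(self.g_squared, self.df_resid))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def expected_frequencies(self) -> pd.DataFrame:
        comp = self.model._compiled
        P = comp.cell_probs(self.params.to_numpy())
        rows = []
        for (tree, cat), prob, obs in zip(comp.cells, P, comp.counts):
            rows.append(
                {
                    "condition": tree,
                    "category": cat,
                    "observed": int(obs),
                    "expected": prob * self.model.data.n(tree),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "MPT model fit (EM maximum likelihood)",
            "=" * 52,
            f"log-likelihood {self.llf:12.4f}    G2 {self.g_squared:8.4f}"
            f"  (df={self.df_resid}, p={self.p_value_fit:.4f})",
            f"converged: {self.converged}   iterations: {self.n_iter}",
            "-" * 52,
            f"{'parameter':<16}{'estimate':>10}{'SE':>10}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_txt = f"{se:10.4f}" if np.isfinite(se) else "        --"
            flag = " (boundary)" if self.at_boundary[name] else ""
            lines.append(f"{name:<16}{self.params[name]:10.4f}{se_txt}{flag}")
        return "\n".join(lines)


@dataclass(frozen=True)
class LRComparison:
    """One nested model comparison: baseline vs restricted, ΔG² on df."""

    restriction: str
    delta_g_squared: float
    df: int
    p_value: float

    def summary(self) -> str:
        return (
            f"{self.restriction}: dG2={self.delta_g_squared:.2f} "
            f"(df={self.df}), p={self.p_value:.4g}"
        )


# ---------------------------------------------------------------------------
# model (statsmodels-style)


class MPTModel:
    """Binary MPT model bound to observed count data.

    Parameters
    ----------
    tree_model
        The structural model (trees, branches, parameter declarations).
    data
        Observed category counts per tree.
    """

    def __init__(self, tree_model: TreeModel, data: CountTable):
        self.tree_model = tree_model
        self.data = data
        self._compiled = _Compiled(tree_model, data)
        k_free = len(self._compiled.free)
        n_indep = tree_model.n_independent_categories
        if k_free > n_indep:
            raise ValueError(
                f"model not identified: {k_free} free parameters but only "
                f"{n_indep} independent categories"
            )

    # ---------------------------------------------------------------- fitting
    def fit(
        self,
        init: Mapping[str, float] | None = None,
        tol: float = 1e-10,
        max_iter: int = 10_000,
        n_restarts: int = 20,
        seed: int = 0,
    ) -> MPTResults:
        """EM maximum likelihood.

        The log-likelihood is checked to be non-decreasing at every
        iteration; convergence is declared when its absolute change drops
        below ``tol``.  On non-convergence, deterministic random restarts
        are attempted and the best run kept.
        """
        comp = self._compiled
        free = comp.free
        if init is not None:
            theta0 = np.array([float(init[n]) for n in free])
            if np.any(theta0 < 0) or np.any(theta0 > 1):
                raise ValueError("initial values outside [0,1]")
        else:
            theta0 = np.full(len(free), 0.5)
        theta0 = np.clip(theta0, BOUND_EPS, 1.0 - BOUND_EPS)

        best = self._run_em(theta0, tol, max_iter)
        if not best[2]:
            # EM can crawl along flat ridges (e.g. weakly identified ratio
            # parameters near 1): polish with a bounded quasi-Newton step,
            # then confirm convergence with EM from the polished point
            best = self._polish(best, tol)
        if not best[2]:
            rng = np.random.default_rng(seed)
            for _ in range(n_restarts):
                cand = self._run_em(rng.uniform(0.05, 0.95, len(free)), tol, max_iter)
                if not cand[2]:
                    cand = self._polish(cand, tol)
                if cand[1] > best[1] or (cand[2] and not best[2]):
                    best = cand
                if best[2]:
                    break
        theta, llf, converged, iters = best

        g2 = max(2.0 * (comp.ll_saturated - llf), 0.0)
        df = self.tree_model.n_independent_categories - len(free)
        at_boundary = pd.Series(
            (theta <= 10 * BOUND_EPS) | (theta >= 1 - 10 * BOUND_EPS), index=free
        )
        bse, flags = self._standard_errors(theta, at_boundary)
        return MPTResults(
            model=self,
            params=pd.Series(theta, index=free),
            bse=bse,
            llf=llf,
            g_squared=g2,
            df_resid=df,
            converged=converged,
            n_iter=iters,
            at_boundary=at_boundary,
            se_flags=flags,
        )

    def _polish(self, state, tol, em_budget: int = 2_000):
        from scipy import optimize

        comp = self._compiled
        theta, ll, _, it = state
        k = len(theta)
        res = optimize.minimize(
            lambda t: -comp.loglik(np.clip(t, BOUND_EPS, 1 - BOUND_EPS)),
            theta,
            method="L-BFGS-B",
            bounds=[(BOUND_EPS, 1 - BOUND_EPS)] * k,
            options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 2_000},
        )
        start = np.clip(res.x, BOUND_EPS, 1 - BOUND_EPS)
        if comp.loglik(start) < ll:
            return state
        cand = self._run_em(start, tol, em_budget)
        if cand[1] >= ll:
            return (cand[0], cand[1], cand[2], it + cand[3])
        return state

    def _run_em(self, theta, tol, max_iter):
        comp = self._compiled
        ll = comp.loglik(theta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            theta = comp.em_step(theta)
            ll_new = comp.loglik(theta)
            if ll_new < ll - 1e-8:
                raise RuntimeError(
                    f"EM log-likelihood decreased ({ll:.10f} -> {ll_new:.10f})"
                )
            if abs(ll_new - ll) < tol:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        return theta, ll, converged, it

    # ------------------------------------------------------- standard errors
    def _standard_errors(self, theta: np.ndarray, at_boundary: pd.Series):
        """SEs from the inverse observed Fisher information (numerical
        Hessian of the log-likelihood at the MLE)."""
        comp = self._compiled
        free = comp.free
        k = len(free)
        flags: dict[str, str] = {}
        if k == 0:
            return pd.Series(dtype=float), flags
        H = np.zeros((k, k))
        h = 1e-5
        f0 = comp.loglik(theta)
        steps = np.minimum(h, np.minimum(theta, 1 - theta) / 2)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = steps[i]
            H[i, i] = (
                comp.loglik(theta + ei) - 2 * f0 + comp.loglik(theta - ei)
            ) / steps[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = steps[j]
                H[i, j] = H[j, i] = (
                    comp.loglik(theta + ei + ej)
                    - comp.loglik(theta + ei - ej)
                    - comp.loglik(theta - ei + ej)
                    + comp.loglik(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
        info = -H
        se = np.full(k, np.nan)
        try:
            cov = np.linalg.inv(info)
            d = np.diag(cov)
            if np.all(d > 0):
                se = np.sqrt(d)
            else:
                flags["information"] = "non-positive-definite information matrix"
        except np.linalg.LinAlgError:
            flags["information"] = "singular information matrix"
        for i, name in enumerate(free):
            if at_boundary[name]:
                se[i] = np.nan
                flags[name] = "estimate at boundary; SE undefined"
        return pd.Series(se, index=free), flags

    # ------------------------------------------------------------ comparison
    def lr_test(
        self,
        restricted_tree: TreeModel,
        description: str = "",
        init: Mapping[str, float] | None = None,
        restricted_init: Mapping[str, float] | None = None,
        **fit_kw,
    ) -> LRComparison:
        base = self.fit(init=init, **fit_kw)
        restricted = MPTModel(restricted_tree, self.data).fit(
            init=restricted_init, **fit_kw
        )
        return compare_models(base, restricted, description)


def compare_models(
    baseline: MPTResults, restricted: MPTResults, description: str = ""
) -> LRComparison:
    """Likelihood-ratio comparison of a restricted model against its baseline.

    Refuses unconverged fits and apparent non-nesting (a restricted model
    fitting *better* than the baseline beyond numerical tolerance).
    """
    if not baseline.converged or not restricted.converged:
        raise ValueError("comparison refused: at least one fit did not converge")
    df = restricted.df_resid - baseline.df_resid
    if df <= 0:
        raise ValueError("restricted model must have fewer free parameters")
    delta = restricted.g_squared - baseline.g_squared
    if delta < -1e-6:
        raise ValueError(
            f"restricted model fits better (dG2={delta:.3g}); models not nested?"
        )
    delta = max(delta, 0.0)
    return LRComparison(
        restriction=description,
        delta_g_squared=delta,
        df=df,
        p_value=float(stats.chi2.sf(delta, df)),
    )
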