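"""Synthetic respondents for faking studies.

Generates respondent-level records with the statistical structure the
analysis assumes: a Bernoulli true status at prevalence ``pi``, an
independent Bernoulli randomization event at probability ``p`` (the
born-in-November/December analogue), deterministic condition allocation
(2:1 crosswise:direct, 1:1 honest:fake-good by default), per-condition
response-strategy mixtures (truthful, fake-good, random responding), and
7-point Likert ratings of perceived sensitivity, confidentiality and ease
of faking calibrated to per-condition target means.

The fake-good strategy always denies under direct questioning.  Under the
crosswise model its sub-model is a configurable mixture over
``honest_equivalent`` (default weight 1: respondents cannot identify a
self-protective option and their answers carry the same information as
honest ones), ``safe_option`` (always pick the lower-risk answer), and
``random``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import datasets
from .design import BOTH_NONE, EXACTLY_ONE, CwmDesign, relative_risk_direction
from .mpt import CountTable

__all__ = [
    "SimulationConfig",
    "default_strategy_mix",
    "simulate",
    "simulate_likert",
    "aggregate",
    "write_records",
    "read_records",
]

RECORD_COLUMNS = [
    "id",
    "technique",
    "instruction",
    "carrier",
    "rand_event",
    "strategy",
    "answer",
    "likert_sensitivity",
    "likert_confidentiality",
    "likert_ease",
]

_CONDITIONS = ["dq_honest", "dq_fake_good", "cwm_honest", "cwm_fake_good"]


def default_strategy_mix(random_rate: float = 0.0) -> dict[str, dict[str, float]]:
    """Per-condition strategy weights: honest conditions answer truthfully,
    fake-good conditions follow the faking strategy; an optional share of
    random responders (literature suggests 5-14% as plausible presets) is
    mixed into every condition."""
    if not 0.0 <= random_rate <= 1.0:
        raise ValueError("random_rate must be in [0,1]")
    keep = 1.0 - random_rate
    return {
        "dq_honest": {"truthful": keep, "fake_good": 0.0, "random": random_rate},
        "cwm_honest": {"truthful": keep, "fake_good": 0.0, "random": random_rate},
        "dq_fake_good": {"truthful": 0.0, "fake_good": keep, "random": random_rate},
        "cwm_fake_good": {"truthful": 0.0, "fake_good": keep, "random": random_rate},
    }


def _reconstructed_sds() -> dict[str, dict[str, float]]:
    """Per-condition Likert SDs reconstructed as SE * sqrt(n) from the
    published summary targets at the published group sizes."""
    out: dict[str, dict[str, float]] = {}
    for item, conds in datasets.LIKERT_TARGETS.items():
        out[item] = {
            cond: se * np.sqrt(datasets.GROUP_SIZES[cond]) for cond, (_, se) in conds.items()
        }
    return out


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic data generator.

    Defaults emulate the street-crossing faking study: prevalence at the
    crosswise honest estimate (the presumed most valid value), p = .158,
    N = 1,946 allocated 2:1 crosswise:direct and 1:1 honest:fake-good,
    honest conditions truthful and fake-good conditions faking, and Likert
    targets at the published per-condition means.
    """

    pi_true: float | dict[str, float] = 0.4553
    p: float = 0.158
    n_total: int = 1946
    cwm_dq_ratio: tuple[float, float] = (2.0, 1.0)
    honest_fake_ratio: tuple[float, float] = (1.0, 1.0)
    group_sizes: dict[str, int] | None = None
    strategy_mix: dict[str, dict[str, float]] = field(default_factory=default_strategy_mix)
    fake_cwm_submodel: dict[str, float] = field(
        default_factory=lambda: {"honest_equivalent": 1.0, "safe_option": 0.0, "random": 0.0}
    )
    likert_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            item: {cond: m for cond, (m, _) in conds.items()}
            for item, conds in datasets.LIKERT_TARGETS.items()
        }
    )
    likert_sds: dict[str, dict[str, float]] = field(default_factory=_reconstructed_sds)
    seed: int = 0

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        for pi in self._pi_map().values():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"prevalence {pi} outside [0,1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0,1]")
        for cond, mix in self.strategy_mix.items():
            total = sum(mix.values())
            if any(w < 0 for w in mix.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"strategy weights for {cond} must be in [0,1] and sum to 1")
        total = sum(self.fake_cwm_submodel.values())
        if any(w < 0 for w in self.fake_cwm_submodel.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("fake_cwm_submodel weights must be in [0,1] and sum to 1")

    def _pi_map(self) -> dict[str, float]:
        if isinstance(self.pi_true, dict):
            return {
                "honest": self.pi_true["honest"],
                "fake_good": self.pi_true["fake_good"],
            }
        return {"honest": float(self.pi_true), "fake_good": float(self.pi_true)}

    def cell_sizes(self) -> dict[str, int]:
        """Deterministic largest-remainder split of ``n_total`` into the
        four cells (or the explicit ``group_sizes`` override)."""
        if self.group_sizes is not None:
            sizes = {c: int(self.group_sizes[c]) for c in _CONDITIONS}
            if any(v < 0 for v in sizes.values()):
                raise ValueError("group sizes must be nonnegative")
            return sizes
        cwm, dq = self.cwm_dq_ratio
        hon, fak = self.honest_fake_ratio
        w_tech = {"dq": dq / (dq + cwm), "cwm": cwm / (dq + cwm)}
        w_inst = {"honest": hon / (hon + fak), "fake_good": fak / (hon + fak)}
        quotas = {
            f"{t}_{i}": self.n_total * w_tech[t] * w_inst[i]
            for t in ("dq", "cwm")
            for i in ("honest", "fake_good")
        }
        sizes = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = self.n_total - sum(sizes.values())
        remainders = sorted(quotas, key=lambda c: quotas[c] - sizes[c], reverse=True)
        for c in remainders[:short]:
            sizes[c] += 1
        return {c: sizes[c] for c in _CONDITIONS}

    # --------------------------------------------------------------- config IO
    def to_json(self, path=None) -> str:
        d = {
            "pi_true": self.pi_true,
            "p": self.p,
            "n_total": self.n_total,
            "cwm_dq_ratio": list(self.cwm_dq_ratio),
            "honest_fake_ratio": list(self.honest_fake_ratio),
            "group_sizes": self.group_sizes,
            "strategy_mix": self.strategy_mix,
            "fake_cwm_submodel": self.fake_cwm_submodel,
            "likert_means": self.likert_means,
            "likert_sds": self.likert_sds,
            "seed": self.seed,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "cwm_dq_ratio" in d:
            d["cwm_dq_ratio"] = tuple(d["cwm_dq_ratio"])
        if "honest_fake_ratio" in d:
            d["honest_fake_ratio"] = tuple(d["honest_fake_ratio"])
        defaults = cls()
        kwargs = {k: v for k, v in d.items() if v is not None or k == "group_sizes"}
        return replace(defaults, **kwargs)


def _calibrated_mu(target_mean: float, sd: float) -> float:
    """Location of the latent normal such that the 1-7 rounded-and-clamped
    response has the target mean (corrects the clamping bias)."""
    if sd == 0.0:
        return target_mean

    def expected(mu: float) -> float:
        edges = (np.arange(1, 7) + 0.5 - mu) / sd
        cdf = stats.norm.cdf(edges)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(np.arange(1, 8) @ probs)

    lo, hi = -30.0, 40.0
    if not expected(lo) <= target_mean <= expected(hi):
        raise ValueError(f"target mean {target_mean} unattainable on the 1-7 scale")
    return float(optimize.brentq(lambda m: expected(m) - target_mean, lo, hi, xtol=1e-10))


def simulate_likert(
    config: SimulationConfig, condition: str, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw the three 7-point Likert items for one condition."""
    out = {}
    for item in ("sensitivity", "confidentiality", "ease"):
        mean = config.likert_means[item][condition]
        if not 1.0 <= mean <= 7.0:
            raise ValueError(f"likert mean {mean} outside [1,7]")
        sd = config.likert_sds[item][condition]
        mu = _calibrated_mu(mean, sd)
        raw = rng.normal(mu, sd, size=n) if sd > 0 else np.full(n, mu)
        out[item] = np.clip(np.rint(raw), 1, 7).astype(int)
    return out


def simulate(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate respondent records; deterministic given the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pi_map = config._pi_map()
    sizes = config.cell_sizes()
    design = CwmDesign(config.p)
    safe = (
        relative_risk_direction(design) if config.fake_cwm_submodel.get("safe_option", 0) > 0
        and config.p != 0.5 else BOTH_NONE
    )

    frames = []
    next_id = 0
    for cond in _CONDITIONS:
        n = sizes[cond]
        if n == 0:
            continue
        technique = "DQ" if cond.startswith("dq") else "CWM"
        instruction = "honest" if cond.endswith("honest") else "fake_good"
        carrier = rng.random(n) < pi_map[instruction]
        rand_event = rng.random(n) < config.p
        mix = config.strategy_mix[cond]
        strategies = rng.choice(
            ["truthful", "fake_good", "random"],
            size=n,
            p=[mix.get("truthful", 0.0), mix.get("fake_good", 0.0), mix.get("random", 0.0)],
        )

        if technique == "DQ":
            truthful_ans = np.where(carrier, "true", "false")
            fake_ans = np.full(n, "false")
            random_ans = np.where(rng.random(n) < 0.5, "true", "false")
        else:
            truthful_ans = np.where(carrier == rand_event, BOTH_NONE, EXACTLY_ONE)
            sub = config.fake_cwm_submodel
            submodel = rng.choice(
                ["honest_equivalent", "safe_option", "random"],
                size=n,
                p=[
                    sub.get("honest_equivalent", 0.0),
                    sub.get("safe_option", 0.0),
                    sub.get("random", 0.0),
                ],
            )
            uniform = np.where(rng.random(n) < 0.5, BOTH_NONE, EXACTLY_ONE)
            fake_ans = np.select(
                [submodel == "honest_equivalent", submodel == "safe_option"],
                [truthful_ans, np.full(n, safe)],
                default=uniform,
            )
            random_ans = np.where(rng.random(n) < 0.5, BOTH_NONE, EXACTLY_ONE)

        answer = np.select(
            [strategies == "truthful", strategies == "fake_good"],
            [truthful_ans, fake_ans],
            default=random_ans,
        )
        likert = simulate_likert(config, cond, n, rng)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(next_id, next_id + n),
                    "technique": technique,
                    "instruction": instruction,
                    "carrier": carrier.astype(int),
                    "rand_event": rand_event.astype(int),
                    "strategy": strategies,
                    "answer": answer,
                    "likert_sensitivity": likert["sensitivity"],
                    "likert_confidentiality": likert["confidentiality"],
                    "likert_ease": likert["ease"],
                }
            )
        )
        next_id += n
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


def aggregate(records: pd.DataFrame) -> CountTable:
    """Collapse respondent records to an answer-frequency CountTable."""
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    counts: dict[str, dict[str, int]] = {}
    meta: dict[str, dict[str, str]] = {}
    grouped = records.groupby(["technique", "instruction", "answer"]).size()
    for (tech, inst, ans), k in grouped.items():
        cond = f"{str(tech).lower()}_{inst}"
        counts.setdefault(cond, {})[str(ans)] = int(k)
        meta[cond] = {"technique": str(tech), "instruction": str(inst)}
    # ensure both categories present per condition (zero-filled)
    for cond in counts:
        cats = ("true", "false") if cond.startswith("dq") else (BOTH_NONE, EXACTLY_ONE)
        for c in cats:
            counts[cond].setdefault(c, 0)
    return CountTable(counts, meta)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)
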