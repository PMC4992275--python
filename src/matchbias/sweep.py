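"""Replicated bias/SE sweeps over an edge's odds ratio.

One sweep fixes a scenario, varies one edge's odds ratio over a grid and, at
every grid point, repeats: simulate a source population, draw the unmatched
and matched designs (sharing the same cases), fit the requested models, and
record each model's exposure log-odds-ratio estimate.  The summary reports,
per grid point and model, the mean bias against the exact causal truth, the
empirical SD of the estimates across replicates, and the mean model-based
standard error — the two SE notions need not coincide, so both are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .estimators import EstimateResult, fit_model
from .population import Population, simulate_population
from .sampling import SamplingError, sample_matched, sample_unmatched
from .scenarios import ScenarioSpec, make_scenario, vary_edge
from .truth import true_causal_logodds

__all__ = [
    "SweepConfig",
    "SweepSummary",
    "BiasSweepStudy",
    "TrendReport",
    "run_replicate",
    "run_sweep",
    "summarize_trends",
]

_SEED_MOD = 2**31  # integer seeds handed to downstream RNGs stay below 2^31


@dataclass(frozen=True)
class SweepConfig:
    """Everything needed to reproduce one sweep bit-for-bit."""

    scenario_id: int
    vary: str  # edge name, e.g. "CE"
    grid: tuple[float, ...] = tuple(float(v) for v in range(1, 11))
    n_reps: int = 1000
    pop_size: int = 100_000
    n_cases: int = 1000
    n_controls: int = 1000
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    master_seed: int = 0
    params: Mapping[str, float] = field(default_factory=dict)
    reuse_population: bool = False  # one fixed population per grid point
    max_failure_rate: float = 0.05

    def base_spec(self) -> ScenarioSpec:
        return make_scenario(self.scenario_id, dict(self.params))


def _derive_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0]) % _SEED_MOD


def run_replicate(
    spec: ScenarioSpec,
    pop_size: int,
    n_cases: int,
    n_controls: int,
    models: Sequence[int],
    seed: int,
    population: Population | None = None,
) -> list[EstimateResult]:
    """One replicate: population -> designs -> fits for the requested models.

    Designs are generated lazily (no matched sample when only models 1-2 are
    requested).  Sampling failures are recorded as non-converged results with
    a note, not raised, so a sweep keeps going.
    """
    pop_seed = _derive_seed(seed, 0)
    sample_seed = _derive_seed(seed, 1)
    if population is None:
        population = simulate_population(spec, pop_size, pop_seed)
    unmatched = matched = None
    results: list[EstimateResult] = []
    need_unmatched = any(m in (1, 2) for m in models)
    need_matched = any(m in (3, 4, 5) for m in models)
    errors: dict[str, str] = {}
    try:
        if need_unmatched:
            unmatched = sample_unmatched(population, n_cases, n_controls, sample_seed)
    except SamplingError as exc:
        errors["unmatched"] = str(exc)
    try:
        if need_matched:
            matched = sample_matched(population, n_cases, sample_seed)
    except SamplingError as exc:
        errors["matched"] = str(exc)
    for m in models:
        design = "unmatched" if m in (1, 2) else "matched"
        if design in errors:
            results.append(
                EstimateResult(m, float("nan"), float("nan"), False, 0,
                               (f"sampling_error:{errors[design]}",))
            )
            continue
        results.append(fit_model(m, unmatched=unmatched, matched=matched))
    return results


@dataclass(frozen=True)
class SweepSummary:
    """Aggregated sweep results.

    ``table`` has one row per (odds ratio, model) with columns
    ``odds_ratio, model_id, beta_true, mean_beta_hat, mean_bias,
    se_empirical, se_model_mean, mc_se, n_reps, n_converged``;
    ``replicates`` keeps every per-replicate estimate.
    """

    config: SweepConfig
    table: pd.DataFrame
    replicates: pd.DataFrame

    @property
    def scenario_id(self) -> int:
        return self.config.scenario_id

    @property
    def varied_edge(self) -> str:
        return self.config.vary

    @property
    def grid(self) -> tuple[float, ...]:
        return self.config.grid

    def summary(self) -> str:
        lines = [
            f"scenario {self.scenario_id}, varying OR({self.varied_edge}) over "
            f"{list(self.grid)}; {self.config.n_reps} replicates, "
            f"{self.config.n_cases} cases / {self.config.n_controls} controls, "
            f"population {self.config.pop_size}",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            self.table.to_csv(sep="\t", index=False, float_format="%.12g")
        )

    def replicates_to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            self.replicates.to_csv(sep="\t", index=False, float_format="%.12g")
        )

    def metadata(self) -> dict:
        meta = asdict(self.config)
        meta["params"] = dict(meta["params"])
        return meta


def run_sweep(config: SweepConfig) -> SweepSummary:
    """Run the full grid x replicate experiment described by ``config``."""
    base = config.base_spec()
    if config.vary not in {f"{p}{c}" for p, c in base.edges}:
        # surfaces the error before any simulation happens
        vary_edge(base, config.vary, 2.0)
    rep_rows = []
    sum_rows = []
    for gi, or_val in enumerate(config.grid):
        spec_g = vary_edge(base, config.vary, or_val)
        beta_true = true_causal_logodds(spec_g).beta
        shared_pop = None
        if config.reuse_population:
            shared_pop = simulate_population(
                spec_g, config.pop_size, _derive_seed(config.master_seed, gi, 0, 0)
            )
        for rep in range(config.n_reps):
            seed = _derive_seed(config.master_seed, gi, rep + 1)
            for res in run_replicate(
                spec_g,
                config.pop_size,
                config.n_cases,
                config.n_controls,
                config.models,
                seed,
                population=shared_pop,
            ):
                rep_rows.append(
                    {
                        "odds_ratio": or_val,
                        "replicate": rep,
                        "model_id": res.model_id,
                        "beta_hat": res.beta_hat,
                        "se_model": res.se_model,
                        "converged": res.converged,
                        "n_used": res.n_used,
                        "beta_true": beta_true,
                    }
                )
        block = pd.DataFrame(rep_rows[-config.n_reps * len(config.models):])
        for m in config.models:
            sub = block[block["model_id"] == m]
            ok = sub[sub["converged"]]
            n_conv = len(ok)
            fail_rate = 1.0 - n_conv / config.n_reps
            if fail_rate > config.max_failure_rate:
                raise RuntimeError(
                    f"model {m} failed in {fail_rate:.1%} of replicates at "
                    f"OR({config.vary})={or_val}; parameters look pathological"
                )
            se_emp = float(ok["beta_hat"].std(ddof=1)) if n_conv > 1 else float("nan")
            sum_rows.append(
                {
                    "odds_ratio": or_val,
                    "model_id": m,
                    "beta_true": beta_true,
                    "mean_beta_hat": float(ok["beta_hat"].mean()),
                    "mean_bias": float(ok["beta_hat"].mean()) - beta_true,
                    "se_empirical": se_emp,
                    "se_model_mean": float(ok["se_model"].mean()),
                    "mc_se": se_emp / np.sqrt(n_conv) if n_conv > 1 else float("nan"),
                    "n_reps": config.n_reps,
                    "n_converged": n_conv,
                }
            )
    return SweepSummary(
        config=config,
        table=pd.DataFrame(sum_rows),
        replicates=pd.DataFrame(rep_rows),
    )


class BiasSweepStudy:
    """Thin object wrapper: ``BiasSweepStudy(config).run()`` -> SweepSummary."""

    def __init__(self, config: SweepConfig):
        self.config = config

    @classmethod
    def from_options(cls, scenario_id: int, vary: str, **kwargs) -> "BiasSweepStudy":
        return cls(SweepConfig(scenario_id=scenario_id, vary=vary, **kwargs))

    def run(self) -> SweepSummary:
        return run_sweep(self.config)


# -- qualitative trend verdicts ----------------------------------------------


@dataclass(frozen=True)
class ModelTrend:
    model_id: int
    monotonicity: str  # "increasing" | "decreasing" | "none"
    zero_bias: bool  # |mean bias| < 3 MC SE at every grid point
    biased_at_max: bool  # |mean bias| > 3 MC SE at the largest odds ratio
    bias_at_max: float
    max_abs_bias: float

    def verdict(self) -> str:
        z = "unbiased" if self.zero_bias else "biased"
        return f"model {self.model_id}: {z}, bias trend {self.monotonicity}"


@dataclass(frozen=True)
class TrendReport:
    """Machine-checkable figure-level claims: signs, monotone trends, SE order."""

    scenario_id: int
    varied_edge: str
    trends: dict[int, ModelTrend]
    se_ranking: dict[float, tuple[int, ...]]  # grid point -> models by rising SE

    def render(self) -> str:
        lines = [f"scenario {self.scenario_id}, varying {self.varied_edge}:"]
        for m in sorted(self.trends):
            lines.append("  " + self.trends[m].verdict())
        for or_val, order in self.se_ranking.items():
            lines.append(
                f"  SE order at OR={or_val:g} (smallest first): "
                + " < ".join(f"m{m}" for m in order)
            )
        return "\n".join(lines)


def summarize_trends(summary: SweepSummary, rho_threshold: float = 0.9) -> TrendReport:
    """Qualitative verdicts per model: monotone bias trend, zero-bias band, SE order.

    Monotonicity is judged by the sign of the Spearman rank correlation
    between the grid and the mean bias (|rho| >= ``rho_threshold``); the
    zero-bias verdict asks the mean bias to sit within 3 Monte-Carlo
    standard errors of zero at every grid point.
    """
    table = summary.table
    grid = list(summary.grid)
    if len(grid) < 2:
        raise ValueError("trend verdicts need at least 2 grid points")
    trends: dict[int, ModelTrend] = {}
    for m in summary.config.models:
        sub = table[table["model_id"] == m].sort_values("odds_ratio")
        bias = sub["mean_bias"].to_numpy()
        mc_se = sub["mc_se"].to_numpy()
        if sub["odds_ratio"].nunique() < 2:
            rho = float("nan")
        else:
            rho = spearmanr(sub["odds_ratio"], bias).statistic
        if np.isnan(rho) or abs(rho) < rho_threshold:
            mono = "none"
        else:
            mono = "increasing" if rho > 0 else "decreasing"
        within = np.abs(bias) < 3.0 * mc_se
        trends[m] = ModelTrend(
            model_id=m,
            monotonicity=mono,
            zero_bias=bool(within.all()),
            biased_at_max=bool(np.abs(bias[-1]) > 3.0 * mc_se[-1]),
            bias_at_max=float(bias[-1]),
            max_abs_bias=float(np.max(np.abs(bias))),
        )
    se_ranking = {}
    for or_val in dict.fromkeys(grid):
        sub = table[table["odds_ratio"] == or_val].sort_values("se_empirical")
        se_ranking[float(or_val)] = tuple(int(m) for m in sub["model_id"])
    return TrendReport(
        scenario_id=summary.scenario_id,
        varied_edge=summary.varied_edge,
        trends=trends,
        se_ranking=se_ranking,
    )
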