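"""Case-control study designs drawn from a source population.

Two designs: simple (unmatched) case-control sampling, and 1:1 individual
exact matching on C.  Cases are drawn from their own seed stream, independent
of the control streams, so the matched and unmatched designs built with the
same seed share an identical case group — the matched design re-uses the
cases and only replaces the control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import Population

__all__ = ["CaseControlSample", "SamplingError", "sample_unmatched", "sample_matched"]

# spawn keys of the per-purpose RNG streams derived from one user seed
_CASE_STREAM, _UNMATCHED_CONTROL_STREAM, _MATCHED_CONTROL_STREAM = 0, 1, 2


class SamplingError(ValueError):
    """Requested sample cannot be drawn from the population."""


@dataclass(frozen=True)
class CaseControlSample:
    """Rows of a drawn study, observed variables only.

    ``data`` columns: ``pair_id`` (pair index for matched designs, -1 for
    unmatched), ``role`` ("case"/"control"), then the observed variables
    (D, E, C).  ``source_index`` preserves each row's index in the source
    population so tests can verify no individual is reused.
    """

    data: pd.DataFrame
    design: str  # "unmatched" | "matched"
    n_cases: int
    n_controls: int
    seed: int

    def cases(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "case"]

    def controls(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "control"]


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _draw_cases(pop: Population, n_cases: int, seed: int) -> np.ndarray:
    d = pop.data["D"].to_numpy()
    case_pool = np.flatnonzero(d == 1)
    if case_pool.size < n_cases:
        raise SamplingError(
            f"requested {n_cases} cases but population has only {case_pool.size} "
            f"individuals with D=1"
        )
    rng = _stream(seed, _CASE_STREAM)
    return rng.choice(case_pool, size=n_cases, replace=False)


def _assemble(
    pop: Population,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    pair_ids_case: np.ndarray,
    pair_ids_control: np.ndarray,
) -> pd.DataFrame:
    obs = pop.observed_data()
    cols = list(obs.columns)
    case_rows = obs.iloc[case_idx].reset_index(drop=True)
    control_rows = obs.iloc[control_idx].reset_index(drop=True)
    case_rows.insert(0, "pair_id", pair_ids_case)
    case_rows.insert(1, "role", "case")
    case_rows["source_index"] = case_idx
    control_rows.insert(0, "pair_id", pair_ids_control)
    control_rows.insert(1, "role", "control")
    control_rows["source_index"] = control_idx
    out = pd.concat([case_rows, control_rows], ignore_index=True)
    return out[["pair_id", "role", *cols, "source_index"]]


def sample_unmatched(
    pop: Population, n_cases: int, n_controls: int, seed: int
) -> CaseControlSample:
    """Simple case-control draw: uniform without replacement within D strata."""
    case_idx = _draw_cases(pop, n_cases, seed)
    d = pop.data["D"].to_numpy()
    control_pool = np.flatnonzero(d == 0)
    if control_pool.size < n_controls:
        raise SamplingError(
            f"requested {n_controls} controls but population has only "
            f"{control_pool.size} individuals with D=0"
        )
    rng = _stream(seed, _UNMATCHED_CONTROL_STREAM)
    control_idx = rng.choice(control_pool, size=n_controls, replace=False)
    no_pairs = np.full(n_cases, -1)
    data = _assemble(pop, case_idx, control_idx, no_pairs, np.full(n_controls, -1))
    return CaseControlSample(data, "unmatched", n_cases, n_controls, int(seed))


def sample_matched(pop: Population, n_cases: int, seed: int) -> CaseControlSample:
    """1:1 exact matching on C.

    Cases are drawn exactly as in :func:`sample_unmatched` (same stream, so
    the two designs share cases for a given seed); each case then receives
    one control drawn uniformly without replacement from the D=0 individuals
    with identical C.
    """
    case_idx = _draw_cases(pop, n_cases, seed)
    d = pop.data["D"].to_numpy()
    c = pop.data["C"].to_numpy()
    case_c = c[case_idx]
    rng = _stream(seed, _MATCHED_CONTROL_STREAM)
    control_idx = np.empty(n_cases, dtype=case_idx.dtype)
    for c_val in (0, 1):
        sel = case_c == c_val
        need = int(sel.sum())
        pool = np.flatnonzero((d == 0) & (c == c_val))
        if pool.size < need:
            raise SamplingError(
                f"control pool exhausted in stratum C={c_val}: need {need}, "
                f"have {pool.size}"
            )
        control_idx[sel] = rng.choice(pool, size=need, replace=False)
    pair_ids = np.arange(n_cases)
    data = _assemble(pop, case_idx, control_idx, pair_ids, pair_ids)
    return CaseControlSample(data, "matched", n_cases, n_cases, int(seed))
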