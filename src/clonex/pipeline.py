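"""Cohort-level orchestration: pair enumeration, filtering, testing, FDR.

Workflow for a cohort of patient clone trees:

1. enumerate unordered gene pairs carried (in at least one tree) by more
   than ``min_informative - 1`` informative patients (default: n > 3);
2. alpha budgeting — drop pairs whose minimum achievable p-value exceeds
   the significance level, so they cannot dilute the FDR correction;
3. run the requested test (placement / occurrence / combined / naive) on
   every retained pair;
4. Benjamini-Hochberg adjustment over the tested pairs and ranking by
   (p, -LLR).

The output table mirrors the standard report layout: rank, gene_pair, n_t,
n, n_cx, n_l, n_s, delta, llr, p, q, with +/-inf serialised as "Inf"/"-Inf".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .baselines import clone_table, log_or_z
from .combined import (combined_m_table, min_possible_p_combined,
                       null_distribution_m, p_combined_exact)
from .occurrence import CohortWeights, occurrence_test
from .placement import (ExclusivityData, ShiftParams, llr_placement,
                        min_possible_p, p_chisq, p_exact)
from .trees import GenePairObservation, PatientSample, collect_pair

__all__ = [
    "PipelineConfig",
    "enumerate_pairs",
    "alpha_budget_filter",
    "bh_adjust",
    "run_cohort",
    "write_results",
    "RESULT_COLUMNS",
]

log = logging.getLogger(__name__)

METHODS = ("placement", "occurrence", "combined", "naive")
RESULT_COLUMNS = ["rank", "gene_pair", "n_t", "n", "n_cx", "n_l", "n_s",
                  "delta", "llr", "p", "q"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a cohort run; mirrored one-to-one by the CLI flags."""

    method: str = "combined"
    min_informative: int = 4
    alpha: float = 0.05
    exact_max_n: int = 12
    mc_samples: int = 1000
    nu: float = 10.0
    seed: int = 0
    min_clone_freq: float = 0.01
    delta_bound: float = 10.0
    binarize_threshold: float = 0.5
    alpha_budget: bool = True
    include_pairless: bool = False

    def shift_params(self) -> ShiftParams:
        return ShiftParams(delta_bound=self.delta_bound,
                           exact_max_n=self.exact_max_n)


def enumerate_pairs(cohort: Sequence[PatientSample],
                    min_informative: int = 4) -> list[tuple[str, str]]:
    """Unordered gene pairs carried by >= min_informative informative patients.

    A pair counts for a patient only when both genes appear together in at
    least one of the patient's trees.
    """
    counts: dict[tuple[str, str], int] = {}
    for p in cohort:
        if not p.is_informative:
            continue
        pairs: set[tuple[str, str]] = set()
        for t in p.trees:
            genes = sorted(t.genes)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    pairs.add((a, b))
        for pr in pairs:
            counts[pr] = counts.get(pr, 0) + 1
    return sorted(pr for pr, c in counts.items() if c >= min_informative)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _combined_tables(n_t: int, cohort_w: CohortWeights, params: ShiftParams,
                     cache: dict | None):
    """(llrs over m, null P(m)) for a given n_t, memoised per cohort run."""
    if cache is not None and n_t in cache:
        return cache[n_t]
    deltas, llrs = combined_m_table(n_t, cohort_w, params)
    pm = null_distribution_m(n_t, cohort_w)
    out = (deltas, llrs, pm)
    if cache is not None:
        cache[n_t] = out
    return out


def _min_possible(obs: GenePairObservation, cohort_w: CohortWeights,
                  config: PipelineConfig, cache: dict | None = None) -> float:
    params = config.shift_params()
    if config.method == "placement":
        if obs.n == 0:
            return 1.0
        if obs.n > config.exact_max_n:
            return 0.0  # continuous chi-squared p can be arbitrarily small
        return min_possible_p(obs.rates, params)
    if config.method == "combined":
        _, llrs, pm = _combined_tables(obs.n_t, cohort_w, params, cache)
        return min_possible_p_combined(obs.n_t, cohort_w, params, llrs, pm)
    return 0.0


def alpha_budget_filter(observations: Sequence[GenePairObservation],
                        cohort_w: CohortWeights, config: PipelineConfig,
                        cache: dict | None = None):
    """Split observations into (retained, removed) by minimum achievable p.

    Pairs whose smallest possible p-value exceeds ``alpha`` can never reach
    significance and are removed before testing and before BH adjustment.
    """
    retained, removed = [], []
    for obs in observations:
        if _min_possible(obs, cohort_w, config, cache) > config.alpha:
            removed.append(obs)
            log.info("alpha budget: removed %s_%s (min p > %.3g)",
                     obs.gene_j, obs.gene_k, config.alpha)
        else:
            retained.append(obs)
    return retained, removed


def _test_pair(obs: GenePairObservation, cohort: Sequence[PatientSample],
               cohort_w: CohortWeights, config: PipelineConfig,
               cache: dict | None = None):
    """Returns (delta, llr, p, flags) for one pair under the configured test."""
    params = config.shift_params()
    flags = {"exact_used": False, "bound_hit": False}
    if config.method == "placement":
        if obs.n == 0:
            return np.nan, np.nan, np.nan, flags
        if obs.n <= config.exact_max_n:
            data = ExclusivityData(obs.rates, obs.outcomes)
            delta, llr = llr_placement(data, params)
            p = p_exact(data, params)
            flags["exact_used"] = True
        else:
            data = ExclusivityData(obs.rates, obs.outcomes_frac)
            delta, llr = llr_placement(data, params)
            p = p_chisq(llr)
    elif config.method == "occurrence":
        s = cohort_w.index(obs.patients)
        res = occurrence_test(s, cohort_w, params)
        delta, llr, p = res.delta_hat, res.llr, res.p
    elif config.method == "combined":
        deltas, llrs, pm = _combined_tables(obs.n_t, cohort_w, params, cache)
        p = p_combined_exact(obs.m, obs.n_t, cohort_w, params, llrs, pm)
        delta, llr = float(deltas[obs.m]), float(llrs[obs.m])
        flags["exact_used"] = True
    elif config.method == "naive":
        table = clone_table(cohort, obs.gene_j, obs.gene_k)
        z, p = log_or_z(table)
        delta, llr = z, z * z
    else:
        raise ValueError(f"unknown method {config.method!r}; "
                         f"choose one of {METHODS}")
    flags["bound_hit"] = bool(np.isinf(delta))
    return delta, llr, p, flags


def run_cohort(cohort: Sequence[PatientSample],
               config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Test every eligible gene pair of a cohort; ranked result table."""
    pairs = enumerate_pairs(cohort, config.min_informative)
    if not pairs:
        log.warning("no gene pairs survive the informative-patient filter")
        return pd.DataFrame(columns=RESULT_COLUMNS)
    cohort_w = CohortWeights.from_cohort(cohort, config.include_pairless)
    observations = [collect_pair(cohort, j, k, config.binarize_threshold)
                    for j, k in pairs]
    cache: dict = {}
    if config.alpha_budget and config.method in ("placement", "combined"):
        observations, removed = alpha_budget_filter(observations, cohort_w,
                                                    config, cache)
    else:
        removed = []
    if not observations:
        log.warning("no gene pairs survive alpha budgeting "
                    "(%d removed)", len(removed))
        return pd.DataFrame(columns=RESULT_COLUMNS)
    rows = []
    for obs in observations:
        delta, llr, p, flags = _test_pair(obs, cohort, cohort_w, config, cache)
        rows.append({"gene_pair": f"{obs.gene_j}_{obs.gene_k}",
                     "n_t": obs.n_t, "n": obs.n, "n_cx": obs.n_cx,
                     "n_l": obs.n_l, "n_s": obs.n_s,
                     "delta": delta, "llr": llr, "p": p, **flags})
    df = pd.DataFrame(rows)
    df = df.dropna(subset=["p"]).reset_index(drop=True)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p", "llr"], ascending=[True, False],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["method"] = config.method
    return df[RESULT_COLUMNS + ["method", "exact_used", "bound_hit"]]


def write_results(df: pd.DataFrame, path) -> None:
    """Write the ranked table as TSV with +/-inf serialised as Inf/-Inf."""
    out = df.copy()
    if "delta" in out.columns:
        out["delta"] = out["delta"].map(
            lambda d: "Inf" if d == np.inf else "-Inf" if d == -np.inf
            else ("" if pd.isna(d) else f"{d:.6g}"))
    out.to_csv(path, sep="\t", index=False)
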