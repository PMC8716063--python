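"""Combined occurrence-and-placement test with a shared shift Delta.

Equating the placement and occurrence tilts (Delta = Delta_p = Delta_o, with
rho = logistic(Delta)) makes the joint log-likelihood of "which patients
carry the pair" and "how the pair is placed in their trees" collapse: the
weights of the selected patients cancel and, writing m for the number of
patients whose trees show the pair as clonally exclusive (star trees count
as exclusive, linear trees as co-occurring), the maximised statistic reduces
to

    LLR(m) = 2 max_rho [ n_t log 2 + m log(1 - rho) + (n_t - m) log rho
                         + log Z - log Z'(rho) ],

where Z = e_{n_t}(w) and Z'(rho) = e_{n_t}(w'(rho)) run over the whole
cohort.  Since LLR depends on the data only through m in {0, ..., n_t}, an
exact p-value follows by enumerating m and computing its null distribution
with a bivariate dynamic programme over (selected count, exclusive count),
using the per-patient factors w_i r_i (selected, exclusive) and
w_i (1 - r_i) (selected, co-occurring).  Ties are again counted at half
weight, as in the exact placement test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_expit
from scipy.stats import chi2

from ._optim import grid_refine_max
from .occurrence import CohortWeights, _log_esp_multi, alt_weights, esp, log_esp
from .placement import ShiftParams

__all__ = [
    "CombinedResult",
    "combined_llr",
    "combined_m_table",
    "null_distribution_m",
    "p_combined_exact",
    "combined_test",
    "min_possible_p_combined",
    "fisher_method_p",
]

_LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class CombinedResult:
    m: int
    n_t: int
    delta_hat: float
    llr: float
    p: float


def _objective_grid(m: int, n_t: int, cohort: CohortWeights,
                    deltas: np.ndarray, log_z: float) -> np.ndarray:
    """Reduced combined objective (half the LLR) on a grid of Delta values."""
    wp = np.stack([alt_weights(cohort.w, cohort.r, d) for d in deltas])
    log_zp = _log_esp_multi(wp, n_t)
    return (n_t * _LOG2 + m * log_expit(-deltas)
            + (n_t - m) * log_expit(deltas) + log_z - log_zp)


def _objective_scalar(m: int, n_t: int, cohort: CohortWeights,
                      delta: float, log_z: float) -> float:
    wp = alt_weights(cohort.w, cohort.r, delta)
    return (n_t * _LOG2 + m * float(log_expit(-delta))
            + (n_t - m) * float(log_expit(delta)) + log_z - log_esp(wp, n_t))


def combined_llr(m: int, n_t: int, cohort: CohortWeights,
                 params: ShiftParams = ShiftParams()):
    """Maximise the reduced combined objective over the shared Delta.

    Returns ``(delta_hat, llr)``.  The objective is identically zero at
    Delta = 0 (where the tilted weights equal the null weights), so
    llr = 2 * max.
    """
    if not 0 <= m <= n_t <= cohort.N:
        raise ValueError(f"need 0 <= m <= n_t <= N, got m={m}, n_t={n_t}, "
                         f"N={cohort.N}")
    if n_t == 0:
        return 0.0, 0.0
    log_z = log_esp(cohort.w, n_t)
    grid = np.linspace(-params.delta_bound, params.delta_bound, 41)
    vals = _objective_grid(m, n_t, cohort, grid, log_z)
    i = int(np.argmax(vals))
    dhat, best = grid_refine_max(
        lambda d: _objective_scalar(m, n_t, cohort, d, log_z),
        grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)], n_grid=3)
    if vals[i] > best:
        dhat, best = float(grid[i]), float(vals[i])
    llr = max(0.0, 2.0 * best)
    if llr <= 1e-12:
        return 0.0, 0.0
    if dhat <= -params.delta_bound + params.delta_report_inf:
        dhat = float("-inf")
    elif dhat >= params.delta_bound - params.delta_report_inf:
        dhat = float("inf")
    return dhat, llr


def combined_m_table(n_t: int, cohort: CohortWeights,
                     params: ShiftParams = ShiftParams()):
    """(delta_hat, llr) for every m in 0..n_t, sharing the cohort normaliser."""
    deltas = np.empty(n_t + 1)
    llrs = np.empty(n_t + 1)
    for m in range(n_t + 1):
        deltas[m], llrs[m] = combined_llr(m, n_t, cohort, params)
    return deltas, llrs


def null_distribution_m(n_t: int, cohort: CohortWeights) -> np.ndarray:
    """Null distribution of the exclusive-tree count m given |S| = n_t.

    P(m) sums, over all n_t-subsets S', the Fisher-weighted probability of
    selecting S' times the probability that exactly m of its patients show
    the pair as exclusive (independent Bernoulli(r_i)).  Computed by a
    bivariate DP over patients; sums to one.
    """
    if not 0 <= n_t <= cohort.N:
        raise ValueError(f"n_t={n_t} out of range for cohort of {cohort.N}")
    if n_t == 0:
        return np.ones(1)
    scale = cohort.w.max(initial=0.0)
    if scale <= 0:
        raise ValueError("cohort has no patient with positive weight")
    ws = cohort.w / scale
    table = np.zeros((n_t + 1, n_t + 1))  # (selected, exclusive)
    table[0, 0] = 1.0
    for wi, ri in zip(ws, cohort.r):
        nxt = table.copy()
        nxt[1:, :] += wi * (1.0 - ri) * table[:-1, :]
        nxt[1:, 1:] += wi * ri * table[:-1, :-1]
        table = nxt
    z = esp(ws, n_t)
    return table[n_t] / z


def p_combined_exact(m_obs: int, n_t: int, cohort: CohortWeights,
                     params: ShiftParams = ShiftParams(),
                     llrs: np.ndarray | None = None,
                     pm: np.ndarray | None = None) -> float:
    """Exact combined p-value over m with the half-tie (mid-p) rule.

    ``llrs`` and ``pm`` may be supplied to reuse a precomputed m-table.
    """
    if llrs is None:
        _, llrs = combined_m_table(n_t, cohort, params)
    if pm is None:
        pm = null_distribution_m(n_t, cohort)
    obs = llrs[m_obs]
    tol = params.tie_rtol * (1.0 + abs(obs))
    diff = llrs - obs
    return float(pm[diff > tol].sum() + 0.5 * pm[np.abs(diff) <= tol].sum())


def min_possible_p_combined(n_t: int, cohort: CohortWeights,
                            params: ShiftParams = ShiftParams(),
                            llrs: np.ndarray | None = None,
                            pm: np.ndarray | None = None) -> float:
    """Smallest combined p-value achievable over m in 0..n_t (alpha budget)."""
    if llrs is None:
        _, llrs = combined_m_table(n_t, cohort, params)
    if pm is None:
        pm = null_distribution_m(n_t, cohort)
    return min(p_combined_exact(m, n_t, cohort, params, llrs, pm)
               for m in range(n_t + 1))


def combined_test(m: int, n_t: int, cohort: CohortWeights,
                  params: ShiftParams = ShiftParams()) -> CombinedResult:
    """Combined test: shared-Delta estimate, LLR and exact p-value."""
    deltas, llrs = combined_m_table(n_t, cohort, params)
    pm = null_distribution_m(n_t, cohort)
    p = p_combined_exact(m, n_t, cohort, params, llrs, pm)
    return CombinedResult(m=m, n_t=n_t, delta_hat=float(deltas[m]),
                          llr=float(llrs[m]), p=p)


def fisher_method_p(p_placement: float, p_occurrence: float) -> float:
    """Fisher's method combination of the two marginal p-values.

    Provided as a secondary summary; the headline combined statistic is the
    joint shared-Delta test above.
    """
    stat = -2.0 * (np.log(max(p_placement, 1e-300))
                   + np.log(max(p_occurrence, 1e-300)))
    return float(chi2.sf(stat, df=4))
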