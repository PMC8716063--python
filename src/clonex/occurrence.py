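"""Gene-pair occurrence test.

Under the null that gene pairs are interchangeable, the probability that a
pair lands in a given patient is proportional to the number of gene pairs
that patient possesses, w_i = C(#genes_i, 2).  Conditioning on the number of
patients carrying the pair, the probability of a specific patient set S is

    P0(S) = prod_{i in S} w_i / Z,   Z = e_{|S|}(w),

the Fisher non-central hypergeometric form, with e_k the elementary
symmetric polynomial computed by dynamic programming in O(N|S|).  Under the
alternative the weights tilt towards co-occurring (linear) or exclusive
(branched/star) topologies,

    w_i' = 2 w_i [rho (1 - r_i) + (1 - rho) r_i],   logit(rho) = Delta_o,

and the LLR of the maximised set probability is referred to chi-squared(1).
An exact version would enumerate C(N, |S|) sets and is not provided.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from ._optim import grid_refine_max
from .placement import ShiftParams, p_chisq
from .trees import PatientSample

__all__ = [
    "CohortWeights",
    "OccurrenceResult",
    "esp",
    "log_esp",
    "alt_weights",
    "log_set_prob",
    "llr_occurrence",
    "occurrence_test",
]


@dataclass(frozen=True, eq=False)
class CohortWeights:
    """Per-patient pair-count weights and background rates for a cohort.

    By default only patients with at least one gene pair (w >= 1) enter the
    null, since a patient with fewer than two genes can never carry a pair;
    zero-weight patients would contribute zero selection probability anyway.
    """

    patients: tuple[str, ...]
    w: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if w.shape != r.shape or w.ndim != 1:
            raise ValueError("w and r must be 1-d and equally long")
        if np.any(w < 0) or np.any((r < 0) | (r > 1)):
            raise ValueError("need w >= 0 and r in [0, 1]")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "r", r)

    @classmethod
    def from_cohort(cls, cohort: Sequence[PatientSample],
                    include_pairless: bool = False) -> "CohortWeights":
        kept = [p for p in cohort if include_pairless or p.w >= 1]
        return cls(tuple(p.patient_id for p in kept),
                   np.array([p.w for p in kept], dtype=float),
                   np.array([p.r for p in kept], dtype=float))

    @property
    def N(self) -> int:
        return self.w.shape[0]

    def index(self, patient_ids: Sequence[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.patients)}
        try:
            return np.array([pos[p] for p in patient_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"patient {exc.args[0]!r} not in cohort weights "
                           "(possibly w = 0)") from None


def esp(weights, k: int) -> float:
    """Elementary symmetric polynomial e_k by the standard O(Nk) recurrence.

    Callers working at cohort scale should rescale the weights (see
    ``log_esp``) to avoid overflow.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} weights")
    e = np.zeros(k + 1)
    e[0] = 1.0
    for wi in w:
        e[1:] = e[1:] + wi * e[:-1]
    return float(e[k])


def log_esp(weights, k: int) -> float:
    """log e_k(weights), computed on weights rescaled by their maximum."""
    w = np.asarray(weights, dtype=float)
    if k == 0:
        return 0.0
    m = w.max(initial=0.0)
    if m <= 0.0:
        return float("-inf")
    val = esp(w / m, k)
    return float(np.log(val) + k * np.log(m)) if val > 0 else float("-inf")


def _log_esp_multi(w_matrix: np.ndarray, k: int) -> np.ndarray:
    """log e_k along the last axis for many weight vectors at once."""
    w = np.asarray(w_matrix, dtype=float)
    if k == 0:
        return np.zeros(w.shape[0])
    m = w.max(axis=1, keepdims=True)
    ws = w / m
    e = np.zeros((w.shape[0], k + 1))
    e[:, 0] = 1.0
    for i in range(w.shape[1]):
        e[:, 1:] = e[:, 1:] + ws[:, i, None] * e[:, :-1]
    with np.errstate(divide="ignore"):
        return np.log(e[:, k]) + k * np.log(m[:, 0])


def alt_weights(w, r, delta_o: float):
    """Tilted weights w' = 2 w [rho (1 - r) + (1 - rho) r], rho = logistic(Delta_o)."""
    rho = expit(delta_o)
    return 2.0 * np.asarray(w, dtype=float) * (
        rho * (1.0 - np.asarray(r, dtype=float)) + (1.0 - rho) * np.asarray(r, dtype=float))


def log_set_prob(s_idx, cohort: CohortWeights, delta_o: float = 0.0) -> float:
    """Log probability of selecting patient set S under the (tilted) null.

    delta_o = 0 gives the null; probabilities over all |S|-subsets sum to 1.
    Returns -inf when a selected patient has zero tilted weight.
    """
    s = np.asarray(s_idx, dtype=int)
    if s.shape[0] > cohort.N:
        raise ValueError("|S| exceeds cohort size")
    wp = alt_weights(cohort.w, cohort.r, delta_o)
    if np.any(wp[s] <= 0.0):
        return float("-inf")
    return float(np.sum(np.log(wp[s])) - log_esp(wp, s.shape[0]))


@dataclass(frozen=True)
class OccurrenceResult:
    delta_hat: float
    llr: float
    p: float
    approximate: bool = True  # chi-squared only; no exact occurrence test


def llr_occurrence(s_idx, cohort: CohortWeights,
                   params: ShiftParams = ShiftParams()):
    """Maximised tilt and LLR statistic of the occurrence test.

    Degenerate cases (S covers the whole cohort, or all rates equal so the
    tilt cancels in the normaliser) yield llr = 0.
    """
    s = np.asarray(s_idx, dtype=int)
    if s.shape[0] == 0:
        raise ValueError("occurrence test needs a non-empty patient set")
    k = s.shape[0]
    if k == cohort.N:
        return 0.0, 0.0
    l0 = log_set_prob(s, cohort, 0.0)

    def obj(delta):
        return log_set_prob(s, cohort, delta)

    dhat, l1 = grid_refine_max(obj, -params.delta_bound, params.delta_bound)
    llr = max(0.0, 2.0 * (l1 - l0))
    if llr <= 1e-12:
        return 0.0, 0.0
    if dhat <= -params.delta_bound + params.delta_report_inf:
        dhat = float("-inf")
    elif dhat >= params.delta_bound - params.delta_report_inf:
        dhat = float("inf")
    return dhat, llr


def occurrence_test(s_idx, cohort: CohortWeights,
                    params: ShiftParams = ShiftParams()) -> OccurrenceResult:
    """Occurrence test with the chi-squared(1) p-value."""
    dhat, llr = llr_occurrence(s_idx, cohort, params)
    return OccurrenceResult(dhat, llr, p_chisq(llr))
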