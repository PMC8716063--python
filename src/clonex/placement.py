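"""Gene-pair placement likelihood-ratio test.

For each patient tumour carrying both genes of a pair, the tree topology
fixes a background clonal exclusivity rate ``r_i`` (the fraction of gene
pairs sitting in different clonal lineages).  Under the null the observed
exclusivity indicator of the pair, ``O_i``, is Bernoulli(r_i).  Under the
alternative every rate is shifted by a common amount Delta on the logit
scale,

    logit(r_i') = logit(r_i) - Delta,

so that negative Delta means enrichment of clonal exclusivity and positive
Delta enrichment of clonal co-occurrence.  The likelihood-ratio statistic
``LLR = 2 (l1 - l0)`` is referred to a chi-squared(1) distribution for large
n, while for small n an exact p-value is computed by enumerating all 2^n
binary exclusivity patterns.  Outcomes tied with the observed statistic are
counted at half weight (a mid-p rule), which makes the exact p-value have
expectation one half under the null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logit
from scipy.stats import chi2

from ._optim import golden_max

__all__ = [
    "ShiftParams",
    "SmoothingParams",
    "ExclusivityData",
    "shift_rate",
    "loglik_null",
    "llr_placement",
    "p_chisq",
    "p_exact",
    "p_monte_carlo",
    "min_possible_p",
    "exact_pvalues_batch",
    "mc_pvalues_batch",
    "chisq_pvalues_batch",
]


@dataclass(frozen=True)
class ShiftParams:
    """Configuration of the bounded Delta optimisation.

    delta_bound
        Half-width of the logit-shift search interval.  Beyond |Delta| of
        about 10 the shifted rates saturate at 0/1, so widening the bound
        changes the maximised likelihood only at machine precision.
    delta_report_inf
        An optimum within this distance of the bound is reported as +/-inf.
    opt_tol
        Interval tolerance of the scalar maximisation.
    exact_max_n
        Largest n for which exact enumeration is attempted; beyond it the
        chi-squared approximation is well calibrated and much cheaper.
    tie_rtol
        Relative tolerance for treating two enumerated LLR values as tied.
    """

    delta_bound: float = 10.0
    delta_report_inf: float = 1e-6
    opt_tol: float = 1e-8
    exact_max_n: int = 12
    tie_rtol: float = 1e-9

    def __post_init__(self):
        if self.delta_bound <= 0:
            raise ValueError("delta_bound must be positive")


@dataclass(frozen=True)
class SmoothingParams:
    """Monte-Carlo smoothing: beta noise on the rates plus resampling.

    Each Monte-Carlo sample perturbs every rate r by a Beta(nu*r, nu*(1-r))
    draw (mean r, overdispersion controlled by nu) before drawing a binary
    outcome; nu -> infinity recovers the exact test.
    """

    nu: float = 10.0
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.nu <= 0 or self.n_samples < 1:
            raise ValueError("need nu > 0 and n_samples >= 1")


@dataclass(frozen=True, eq=False)
class ExclusivityData:
    """Informative per-patient rates and outcomes for one gene pair.

    Rates must lie strictly inside (0, 1): patients with linear (r=0) or
    star (r=1) topologies carry no placement information and must be removed
    by the caller before constructing this object.  Outcomes may be
    fractional in [0, 1] when averaging over posterior tree samples.
    """

    rates: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        o = np.asarray(self.outcomes, dtype=float)
        if r.ndim != 1 or o.shape != r.shape:
            raise ValueError("rates and outcomes must be 1-d and equally long")
        if np.any((r <= 0.0) | (r >= 1.0)):
            raise ValueError("rates must lie strictly in (0, 1); "
                             "filter uninformative patients first")
        if np.any((o < 0.0) | (o > 1.0)):
            raise ValueError("outcomes must lie in [0, 1]")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "outcomes", o)

    @property
    def n(self) -> int:
        return self.rates.shape[0]

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.outcomes == 0.0) | (self.outcomes == 1.0)))

    def binarized(self, threshold: float = 0.5) -> "ExclusivityData":
        """Round fractional outcomes to {0, 1} at the given threshold."""
        return ExclusivityData(self.rates,
                               (self.outcomes >= threshold).astype(float))


def shift_rate(r, delta):
    """Shift an exclusivity rate by ``delta`` on the logit scale.

    r' = logistic(logit(r) - delta).  The boundary rates 0 and 1 are fixed
    points for any finite delta (linear and star topologies are unaffected
    by the shift).
    """
    r_arr = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        out = expit(logit(r_arr) - delta)
    out = np.where(r_arr <= 0.0, 0.0, np.where(r_arr >= 1.0, 1.0, out))
    return float(out) if out.ndim == 0 else out


def loglik_null(data: ExclusivityData) -> float:
    """Null log-likelihood  sum_i O_i log r_i + (1 - O_i) log(1 - r_i)."""
    if data.n == 0:
        return 0.0
    r, o = data.rates, data.outcomes
    return float(np.sum(o * np.log(r) + (1.0 - o) * np.log1p(-r)))


def _batch_llr(rates: np.ndarray, outcomes: np.ndarray, params: ShiftParams):
    """Vectorised (delta_hat, llr) over rows of (rates, outcomes).

    Each row is an independent instance with the same n.  The objective is a
    sum of concave log-logistic terms, so golden-section search converges to
    the global maximum.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    outcomes = np.atleast_2d(np.asarray(outcomes, dtype=float))
    a = logit(rates)
    o = outcomes
    nb = rates.shape[0]

    def obj(delta):
        x = a - delta[:, None]
        return np.sum(o * log_expit(x) + (1.0 - o) * log_expit(-x), axis=1)

    l0 = obj(np.zeros(nb))
    dhat, l1 = golden_max(obj, -params.delta_bound, params.delta_bound,
                          (nb,), params.opt_tol)
    llr = 2.0 * (l1 - l0)
    return dhat, np.maximum(llr, 0.0)


def _report_delta(dhat: float, llr: float, params: ShiftParams) -> float:
    if llr <= 1e-12:
        return 0.0
    if dhat <= -params.delta_bound + params.delta_report_inf:
        return float("-inf")
    if dhat >= params.delta_bound - params.delta_report_inf:
        return float("inf")
    return dhat


def llr_placement(data: ExclusivityData,
                  params: ShiftParams = ShiftParams()):
    """Maximum-likelihood shift and LLR statistic for the placement test.

    Returns ``(delta_hat, llr)``; ``delta_hat`` is reported as +/-inf when
    the bounded optimisation terminates at the search boundary.
    """
    if data.n == 0:
        raise ValueError("placement test needs at least one informative patient")
    dhat, llr = _batch_llr(data.rates[None, :], data.outcomes[None, :], params)
    return _report_delta(float(dhat[0]), float(llr[0]), params), float(llr[0])


def p_chisq(llr: float) -> float:
    """Asymptotic p-value: upper tail of chi-squared with one df."""
    if llr < -1e-8:
        raise ValueError(f"negative LLR statistic: {llr}")
    return float(chi2.sf(max(llr, 0.0), df=1))


def _enumerate_outcomes(n: int) -> np.ndarray:
    idx = np.arange(2 ** n)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def _exact_table(rates: np.ndarray, params: ShiftParams):
    """LLR statistic and null probability of every binary outcome vector."""
    n = rates.shape[0]
    vecs = _enumerate_outcomes(n)
    tiled = np.broadcast_to(rates, vecs.shape)
    _, llr_all = _batch_llr(tiled, vecs, params)
    logp = vecs @ np.log(rates) + (1.0 - vecs) @ np.log1p(-rates)
    return vecs, llr_all, np.exp(logp)


def _half_tie_p(llr_all, probs, llr_obs, tie_rtol):
    tol = tie_rtol * (1.0 + abs(llr_obs))
    diff = llr_all - llr_obs
    return float(probs[diff > tol].sum() + 0.5 * probs[np.abs(diff) <= tol].sum())


def p_exact(data: ExclusivityData, params: ShiftParams = ShiftParams()) -> float:
    """Exact placement p-value by enumeration of all 2^n binary patterns.

    Requires binary outcomes (single-tree patients, or binarised posterior
    fractions) and n no larger than ``params.exact_max_n``.
    """
    if data.n == 0:
        raise ValueError("exact test needs at least one informative patient")
    if data.n > params.exact_max_n:
        raise ValueError(
            f"n={data.n} exceeds the exact enumeration limit "
            f"({params.exact_max_n}); use p_chisq or p_monte_carlo")
    if not data.is_binary:
        raise ValueError("exact test is defined on binary outcomes; "
                         "binarize fractional outcomes first")
    _, llr_all, probs = _exact_table(data.rates, params)
    obs_idx = int(np.round(data.outcomes @ (2.0 ** np.arange(data.n))))
    return _half_tie_p(llr_all, probs, llr_all[obs_idx], params.tie_rtol)


def min_possible_p(rates, params: ShiftParams = ShiftParams()) -> float:
    """Smallest exact p-value achievable over all 2^n outcome vectors.

    Used for alpha budgeting: a gene pair whose minimum possible p-value
    already exceeds the significance level can never become significant and
    is removed before testing to protect the multiple-testing correction.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or rates.shape[0] == 0:
        raise ValueError("rates must be a non-empty 1-d array")
    if rates.shape[0] > params.exact_max_n:
        raise ValueError(f"n={rates.shape[0]} exceeds the exact enumeration "
                         f"limit ({params.exact_max_n})")
    _, llr_all, probs = _exact_table(rates, params)
    # p as a function of the observed vector, vectorised via sorting
    order = np.argsort(llr_all)
    ll = llr_all[order]
    cum = np.concatenate([[0.0], np.cumsum(probs[order])])
    total = cum[-1]
    tol = params.tie_rtol * (1.0 + np.abs(llr_all))
    hi = np.searchsorted(ll, llr_all + tol, side="right")
    lo = np.searchsorted(ll, llr_all - tol, side="left")
    greater = total - cum[hi]
    ties = cum[hi] - cum[lo]
    return float(np.min(greater + 0.5 * ties))


def p_monte_carlo(data: ExclusivityData,
                  params: ShiftParams = ShiftParams(),
                  smooth: SmoothingParams = SmoothingParams()) -> float:
    """Monte-Carlo smoothed placement p-value.

    Each sample perturbs the rates with beta noise, draws binary outcomes at
    the perturbed rates, and recomputes the LLR at those rates; the p-value
    is the fraction of samples with LLR strictly above the observed one.
    """
    if data.n == 0:
        raise ValueError("Monte-Carlo test needs at least one informative patient")
    rng = np.random.default_rng(smooth.seed)
    return float(mc_pvalues_batch(data.rates[None, :], data.outcomes[None, :],
                                  params, smooth, rng)[0])


# ---------------------------------------------------------------------------
# batch helpers used by the simulation studies
# ---------------------------------------------------------------------------

def chisq_pvalues_batch(rates, outcomes, params: ShiftParams = ShiftParams()):
    """Chi-squared placement p-values for many instances at once."""
    _, llr = _batch_llr(rates, outcomes, params)
    return chi2.sf(llr, df=1)


def exact_pvalues_batch(rates, outcomes, params: ShiftParams = ShiftParams(),
                        max_rows: int = 1 << 17):
    """Exact placement p-values for many instances sharing the same n.

    Enumeration is stacked across replicates and processed in chunks of at
    most ``max_rows`` rows to bound memory.
    """
    rates = np.asarray(rates, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    reps, n = rates.shape
    if n > params.exact_max_n:
        raise ValueError(f"n={n} exceeds the exact enumeration limit")
    vecs = _enumerate_outcomes(n)
    k = vecs.shape[0]
    obs_idx = np.round(outcomes @ (2.0 ** np.arange(n))).astype(int)
    out = np.empty(reps)
    step = max(1, max_rows // k)
    for start in range(0, reps, step):
        stop = min(start + step, reps)
        rc = rates[start:stop]
        c = rc.shape[0]
        stacked_r = np.repeat(rc, k, axis=0)
        stacked_o = np.tile(vecs, (c, 1))
        _, llr = _batch_llr(stacked_r, stacked_o, params)
        llr = llr.reshape(c, k)
        logp = (vecs @ np.log(rc).T + (1.0 - vecs) @ np.log1p(-rc).T).T
        probs = np.exp(logp)
        llr_obs = llr[np.arange(c), obs_idx[start:stop]]
        tol = params.tie_rtol * (1.0 + np.abs(llr_obs))[:, None]
        diff = llr - llr_obs[:, None]
        out[start:stop] = (np.sum(probs * (diff > tol), axis=1)
                           + 0.5 * np.sum(probs * (np.abs(diff) <= tol), axis=1))
    return out


def mc_pvalues_batch(rates, outcomes, params: ShiftParams,
                     smooth: SmoothingParams, rng: np.random.Generator,
                     max_rows: int = 1 << 17):
    """Monte-Carlo smoothed p-values for many instances sharing the same n."""
    rates = np.asarray(rates, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    reps, n = rates.shape
    m = smooth.n_samples
    _, llr_obs = _batch_llr(rates, outcomes, params)
    out = np.empty(reps)
    step = max(1, max_rows // m)
    eps = 1e-12
    for start in range(0, reps, step):
        stop = min(start + step, reps)
        rc = rates[start:stop]
        c = rc.shape[0]
        a = np.repeat(smooth.nu * rc, m, axis=0)
        b = np.repeat(smooth.nu * (1.0 - rc), m, axis=0)
        rp = np.clip(rng.beta(a, b), eps, 1.0 - eps)
        draws = (rng.random(rp.shape) < rp).astype(float)
        _, llr_s = _batch_llr(rp, draws, params)
        llr_s = llr_s.reshape(c, m)
        out[start:stop] = np.mean(llr_s > llr_obs[start:stop, None], axis=1)
    return out
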