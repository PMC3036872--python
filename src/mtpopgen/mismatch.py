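"""Mismatch distributions and the sudden-expansion demographic model.

The mismatch distribution is the histogram of pairwise nucleotide difference
counts.  Under the sudden-expansion model a population at equilibrium with
scaled size theta0 grew instantaneously to theta1 at a time tau in the past
(tau in units of mutational time, tau = 2*u*t).  The probability that a
random pair differs at i sites is then

    F_i(tau, theta0, theta1) = Fhat_i(theta1)
        + exp(-tau (theta1 + 1)/theta1)
          * sum_{j=0}^{i} tau^j / j! [Fhat_{i-j}(theta0) - Fhat_{i-j}(theta1)]

with the geometric equilibrium Fhat_j(theta) = theta^j / (1+theta)^(j+1).
The three parameters are fitted by (unweighted) non-linear least squares on
the observed histogram with bounded multi-start local optimisation; the
theta1 upper bound 99999 acts as the conventional "effectively infinite"
sentinel when theta1 is unidentifiable.  Goodness of fit (sum of squared
deviations, and Harpending's raggedness index) and parameter confidence
intervals come from a parametric coalescent bootstrap under the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from . import sim as _sim

__all__ = [
    "MismatchFit",
    "TimeScaling",
    "observed_mismatch",
    "expected_mismatch",
    "raggedness",
    "sum_squared_deviations",
    "fit_sudden_expansion",
    "tau_to_years",
]

THETA1_CAP = 99999.0
_BOUNDS = ((0.0, 50.0), (0.0, 50.0), (1e-6, THETA1_CAP))  # tau, theta0, theta1


@dataclass
class TimeScaling:
    """Converts mutational time to calendar years.

    ``u = mu_site_per_year * L * generation_years`` is the mutation rate per
    sequence per generation; tau = 2*u*t gives t = tau / (2u) generations.
    """

    mu_site_per_year: float = 1.9e-7
    L: int = 993
    generation_years: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_site_per_year, self.L, self.generation_years) <= 0:
            raise ValueError("all scaling fields must be positive")

    @property
    def u(self) -> float:
        return self.mu_site_per_year * self.L * self.generation_years


@dataclass
class MismatchFit:
    obs: np.ndarray
    tau: float
    theta0: float
    theta1: float
    SSD: float
    raggedness: float
    ci95_tau: tuple[float, float]
    p_SSD: float
    p_raggedness: float
    n_boot: int


def observed_mismatch(diff_matrix: np.ndarray) -> np.ndarray:
    """Relative frequencies of pairwise difference counts 0..d_max."""
    d = np.asarray(diff_matrix)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square difference matrix over >= 2 sequences")
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("difference matrix must be symmetric and non-negative")
    iu = np.triu_indices(d.shape[0], k=1)
    counts = np.rint(d[iu]).astype(int)
    hist = np.bincount(counts)
    return hist / hist.sum()


def _geometric(theta: float, d_max: int) -> np.ndarray:
    j = np.arange(d_max + 1)
    if theta == 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    # theta^j/(1+theta)^(j+1) in logs for large theta
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def expected_mismatch(tau: float, theta0: float, theta1: float, d_max: int) -> np.ndarray:
    """Model mismatch probabilities for difference classes 0..d_max.

    The vector is a truncation of a distribution over all non-negative
    counts; it is deliberately not renormalised, so the missing tail mass is
    ``1 - vector.sum()``.  ``theta1 = 0`` is outside the domain of the
    transient term (treated as the equilibrium of theta0 when tau = 0 makes
    the model collapse); the fitter keeps theta1 >= 1e-6 for this reason.
    """
    if min(tau, theta0, theta1) < 0:
        raise ValueError("parameters must be non-negative")
    F1 = _geometric(theta1, d_max)
    if tau == 0.0:
        return _geometric(theta0, d_max)
    if theta1 == 0.0:
        raise ValueError("theta1 = 0 with tau > 0 is outside the model domain")
    F0 = _geometric(theta0, d_max)
    j = np.arange(d_max + 1)
    log_pois = j * np.log(tau) - gammaln(j + 1)
    w = np.exp(-tau * (theta1 + 1.0) / theta1 + log_pois)
    delta = F0 - F1
    # sum_{j<=i} w_j * delta_{i-j}: a truncated convolution
    conv = np.convolve(w, delta)[: d_max + 1]
    # cancellation can leave values a few ulp below zero
    return np.maximum(F1 + conv, 0.0)


def raggedness(obs: np.ndarray) -> float:
    """Harpending's raggedness index: the sum of squared successive
    differences of the class frequencies, with a zero appended after the last
    class (so a single-class histogram [1.0] scores 1.0)."""
    x = np.asarray(obs, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a 1-D frequency vector")
    padded = np.concatenate([x, [0.0]])
    return float((np.diff(padded) ** 2).sum())


def sum_squared_deviations(obs: np.ndarray, tau: float, theta0: float, theta1: float) -> float:
    exp_v = expected_mismatch(tau, theta0, theta1, len(obs) - 1)
    return float(((obs - exp_v) ** 2).sum())


def _fit_once(obs: np.ndarray, x0: np.ndarray) -> tuple[np.ndarray, float]:
    def objective(x):
        return sum_squared_deviations(obs, *x)

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=_BOUNDS,
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 500},
    )
    return res.x, float(res.fun)


def _fit_multistart(obs: np.ndarray, rng: np.random.Generator, n_starts: int = 10):
    mean_diffs = float((np.arange(len(obs)) * obs).sum())
    starts = [
        np.array([max(mean_diffs, 0.1), 1e-3, THETA1_CAP]),  # method of moments
        np.array([max(mean_diffs, 0.1), 1e-3, max(5.0 * mean_diffs, 1.0)]),
        np.array([max(mean_diffs / 2.0, 0.1), mean_diffs, mean_diffs]),
    ]
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    rng.uniform(0.0, min(2.0 * mean_diffs + 1.0, 50.0)),
                    rng.uniform(0.0, 5.0),
                    np.exp(rng.uniform(np.log(1e-2), np.log(THETA1_CAP))),
                ]
            )
        )
    best_x, best_f = None, np.inf
    for x0 in starts:
        try:
            x, f = _fit_once(obs, x0)
        except Exception:
            continue
        if f < best_f:
            best_x, best_f = x, f
    if best_x is None:
        raise RuntimeError("sudden-expansion fit failed from every start")
    return best_x, best_f


def fit_sudden_expansion(
    obs: np.ndarray,
    n: int,
    seed: int | None = None,
    n_boot: int = 200,
    n_starts: int = 10,
) -> MismatchFit:
    """Fit (tau, theta0, theta1) to an observed mismatch histogram.

    ``n`` is the number of sequences behind ``obs`` and sets the sample size
    of the parametric bootstrap, whose replicates are coalescent simulations
    under the fitted model refitted the same way.  The bootstrap supplies the
    95 % percentile interval for tau and the goodness-of-fit p-values
    (fraction of replicates with SSD, or raggedness, at least the observed).
    """
    obs = np.asarray(obs, dtype=float)
    if n < 3:
        raise ValueError("mismatch fitting needs >= 3 sequences")
    if abs(obs.sum() - 1.0) > 1e-6:
        raise ValueError("observed mismatch must sum to 1")
    rng = np.random.default_rng(seed)
    (tau, th0, th1), ssd = _fit_multistart(obs, rng, n_starts)
    r_obs = raggedness(obs)

    taus, ssds, rags = [], [], []
    config = _sim.SimConfig(
        scenario="sudden_expansion", n=n, theta0=max(th0, 0.0), theta1=max(th1, 1e-6), tau=tau
    )
    for _ in range(n_boot):
        d = _sim.simulate_pairwise_diffs(config, rng)
        ob = observed_mismatch(d)
        try:
            (tb, _, _), sb = _fit_multistart(ob, rng, n_starts=4)
        except RuntimeError:
            continue
        taus.append(tb)
        ssds.append(sb)
        rags.append(raggedness(ob))
    if n_boot and not taus:
        warnings.warn("all bootstrap replicates failed; CIs unavailable")
    ci = (
        tuple(np.percentile(taus, [2.5, 97.5])) if taus else (float("nan"), float("nan"))
    )
    p_ssd = float(np.mean(np.asarray(ssds) >= ssd)) if ssds else float("nan")
    p_rag = float(np.mean(np.asarray(rags) >= r_obs)) if rags else float("nan")
    return MismatchFit(obs, float(tau), float(th0), float(th1), ssd, r_obs, ci, p_ssd, p_rag, len(taus))


def tau_to_years(tau: float, scaling: TimeScaling) -> float:
    """Calendar years since expansion: t = tau / (2u) generations."""
    return tau / (2.0 * scaling.u) * scaling.generation_years
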